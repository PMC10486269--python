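# Default star-allele activity values and phenotype cut-points.
#
# Activity values follow the published DPWG/CPIC conventions: "*1" is the
# fully functional reference (activity 1), null alleles score 0, and
# decreased-function alleles score fractional values.  CYP2C19*17
# (increased function) is given activity 1.5 so that the activity-score
# intervals below reproduce the diplotype-class scheme: two null alleles ->
# PM, one null -> IM (incl. *2/*17 at 1.5), *17/*17 -> UM, anything else
# (incl. *1/*17) -> NM.  Duplication alleles carry an explicit "xN" entry;
# unlisted "*<k>x<n>" names fall back to n times the base-allele activity.
CYP2C19:
  alleles:
    "*1": 1.0
    "*2": 0.0
    "*3": 0.0
    "*17": 1.5
  cutpoints:
    pm_max: 0.0
    im_max: 1.5
    nm_max: 2.5
CYP2D6:
  alleles:
    "*1": 1.0
    "*2": 1.0
    "*3": 0.0
    "*4": 0.0
    "*5": 0.0   # whole-gene deletion
    "*6": 0.0
    "*9": 0.5
    "*10": 0.25
    "*41": 0.5
    "*1xN": 2.0
    "*2xN": 2.0
  cutpoints:
    pm_max: 0.0
    im_max: 1.0
    nm_max: 2.25
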