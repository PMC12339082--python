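# Mutant/wild-type multiplicative effect profiles per age group.
#
# Each scaling is the planted ratio of the mutant group mean to the
# wild-type group mean for one measure, encoding the reported cohort
# differences of the progeria mouse study this pipeline reproduces:
#   growth-plate (resting+proliferative) thickness:  -18% (8W), -25% (15W)
#   primary-spongiosa BV/TV:                         -23% (8W), -38% (15W)
#   secondary-spongiosa BV/TV:                       -36% (8W), -49% (15W, ns)
#   secondary-spongiosa Tb.Th:                       -21% (8W), -24% (15W)
# Primary Tb.Th, epiphyseal structure and zone mineralization (ca_mean) carry
# no effect: mineral content and primary Tb.Th did not differ between
# genotypes.  The empty-lacuna increase is reported only graphically; the
# factor below is a plausible default (wild-type baseline in
# `empty_fraction_pct`), not a transcribed number.
#
# Cohort sizes are those of the histomorphometric analyses (one 8-week
# wild-type animal lacked sufficient trabecular area and was excluded).

8W:
  n_wt: 19
  n_mut: 18
  empty_fraction_pct: 8.0
  counted_lacunae_mean: 1400
  effects:
    growth_plate_thickness: 0.82
    bvtv_primary: 0.77
    tbth_primary: 1.00
    bvtv_secondary: 0.64
    tbth_secondary: 0.79
    bvtv_epiphysis: 1.00
    tbth_epiphysis: 1.00
    ca_mean: 1.00
    empty_fraction: 2.2

15W:
  n_wt: 7
  n_mut: 7
  empty_fraction_pct: 10.0
  counted_lacunae_mean: 2300
  effects:
    growth_plate_thickness: 0.75
    bvtv_primary: 0.62
    tbth_primary: 1.00
    bvtv_secondary: 0.51
    tbth_secondary: 0.76
    bvtv_epiphysis: 1.00
    tbth_epiphysis: 1.00
    ca_mean: 1.00
    empty_fraction: 1.8
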