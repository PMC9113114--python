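# Source-column aliases for the 18 canonical cerebellar ROIs.
#
# Each canonical ROI maps to a list of alternatives tried in order after the
# canonical name itself.  An alternative given as a plain string is a single
# renamed column; an alternative given as a list is a set of finer
# segmentation labels that are SUMMED into the composite (all parts must be
# present for the alternative to apply).  Matching is case-insensitive.
#
# The default entries cover the label scheme of common automated cerebellum
# parcellation tools, which emit per-lobule labels finer than the composite
# reporting convention used here (Crus II and lobule VIIB joint; vermal
# lobules grouped I-V, VI-VII, VIII-X; corpus medullare = white matter).
# Template versions differ in how VIIB is labelled, so edit or extend this
# file rather than renaming your columns.

left_lobules_I_V:
  - [left_i_iii, left_iv, left_v]
  - [left i-iii, left iv, left v]
left_lobule_VI:
  - left_vi
  - left vi
left_crus_I:
  - left_crus_i
  - left crus i
left_crus_II_VIIB:
  - [left_crus_ii, left_viib]
  - [left crus ii, left viib]
left_lobule_VIII:
  - left_viii
  - [left_viiia, left_viiib]
  - left viii
left_lobule_IX:
  - left_ix
  - left ix
left_lobule_X:
  - left_x
  - left x
right_lobules_I_V:
  - [right_i_iii, right_iv, right_v]
  - [right i-iii, right iv, right v]
right_lobule_VI:
  - right_vi
  - right vi
right_crus_I:
  - right_crus_i
  - right crus i
right_crus_II_VIIB:
  - [right_crus_ii, right_viib]
  - [right crus ii, right viib]
right_lobule_VIII:
  - right_viii
  - [right_viiia, right_viiib]
  - right viii
right_lobule_IX:
  - right_ix
  - right ix
right_lobule_X:
  - right_x
  - right x
vermis_I_V:
  - vermal_I_V
  - [vermis_i_iii, vermis_iv, vermis_v]
vermis_VI_VII:
  - vermal_VI_VII
  - [vermis_vi, vermis_vii]
vermis_VIII_X:
  - vermal_VIII_X
  - [vermis_viii, vermis_ix, vermis_x]
white_matter:
  - corpus_medullare
  - corpus medullare
  - cerebellar_white_matter
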