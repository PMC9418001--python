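# Van Krevelen compound-class boundaries (rectangles in H/C x O/C space).
#
# These are the rectangular class windows commonly used for DOM Van
# Krevelen classification (lipid / protein / lignin / tannin / condensed
# aromatic etc. regions of the diagram).  Exact boundaries vary between
# studies; they are configuration data here, not code constants — edit
# this file (or pass your own table) to match a different convention.
#
# All intervals are half-open: lo <= value < hi.  Points covered by no
# rectangle fall into the "other" class.  Rectangles must not overlap
# (checked by the test suite).
classes:
  - name: lipid
    hc: [1.5, 2.5]
    oc: [0.0, 0.3]
  - name: unsaturated_hydrocarbon
    hc: [0.7, 1.5]
    oc: [0.0, 0.3]
  - name: condensed_aromatic
    hc: [0.2, 0.7]
    oc: [0.0, 0.3]
  - name: protein
    hc: [1.5, 2.3]
    oc: [0.3, 0.55]
  - name: lignin
    hc: [0.7, 1.5]
    oc: [0.3, 0.55]
  - name: amino_sugar
    hc: [1.5, 2.2]
    oc: [0.55, 0.7]
  - name: carbohydrate
    hc: [1.5, 2.5]
    oc: [0.7, 1.51]
  - name: tannin
    hc: [0.5, 1.5]
    oc: [0.7, 1.51]
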