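# Default signed weight fixture: 38 directed edges over the 28-concept map
# (27 risk factors C1..C27 plus the central GC outcome concept C28).
#
# This matrix is a documented, plausible configuration artifact, NOT the
# learned matrix of the original study (whose numeric weights were never
# published in machine-readable form). Magnitudes correspond to centroids
# of the linguistic bank (0.5 ~ medium, 0.7 ~ high, 0.9 ~ very high). All
# 27 factor-to-outcome edges are rated high or very high — the factors were
# selected as *major* risk factors — and signs follow the published risk
# directions: protective factors (vegetables, fruit, milk, allergy history,
# cardiovascular history, physical activity) carry negative edges into GC,
# hazards carry positive ones.
#
# 27 edges feed the central GC node; 11 further edges encode plausible
# factor-to-factor interactions (e.g. H. pylori infection inflames the
# mucosa). Whether the original map contained factor-to-factor edges is not
# documented; this set is an explicit modeling choice.
edges:
  # risk factor -> GC
  - {source: C1,  target: C28, weight:  0.7}
  - {source: C2,  target: C28, weight:  0.7}
  - {source: C3,  target: C28, weight:  0.7}
  - {source: C4,  target: C28, weight:  0.9}
  - {source: C5,  target: C28, weight: -0.7}
  - {source: C6,  target: C28, weight:  0.7}
  - {source: C7,  target: C28, weight:  0.7}
  - {source: C8,  target: C28, weight:  0.9}
  - {source: C9,  target: C28, weight:  0.9}
  - {source: C10, target: C28, weight: -0.7}
  - {source: C11, target: C28, weight:  0.7}
  - {source: C12, target: C28, weight: -0.7}
  - {source: C13, target: C28, weight:  0.7}
  - {source: C14, target: C28, weight:  0.7}
  - {source: C15, target: C28, weight: -0.7}
  - {source: C16, target: C28, weight:  0.7}
  - {source: C17, target: C28, weight:  0.7}
  - {source: C18, target: C28, weight: -0.7}
  - {source: C19, target: C28, weight:  0.7}
  - {source: C20, target: C28, weight:  0.9}
  - {source: C21, target: C28, weight: -0.7}
  - {source: C22, target: C28, weight:  0.7}
  - {source: C23, target: C28, weight:  0.7}
  - {source: C24, target: C28, weight:  0.7}
  - {source: C25, target: C28, weight:  0.9}
  - {source: C26, target: C28, weight:  0.7}
  - {source: C27, target: C28, weight:  0.9}
  # factor -> factor interactions
  - {source: C8,  target: C23, weight:  0.5}
  - {source: C9,  target: C26, weight:  0.5}
  - {source: C25, target: C26, weight:  0.7}
  - {source: C25, target: C27, weight:  0.7}
  - {source: C23, target: C27, weight:  0.5}
  - {source: C26, target: C27, weight:  0.5}
  - {source: C13, target: C3,  weight:  0.5}
  - {source: C14, target: C3,  weight:  0.3}
  - {source: C5,  target: C3,  weight: -0.3}
  - {source: C6,  target: C26, weight:  0.3}
  - {source: C24, target: C26, weight:  0.3}
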