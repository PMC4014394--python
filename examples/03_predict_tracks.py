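"""Compute the two internal per-residue tracks and render a protein report.

Low complexity: Wootton-Federhen window entropy (K2, bits); a 12-residue
window at or below 2.2 bits seeds a low-complexity contig.  Disorder: the
TOP-IDP propensity scale, smoothed and logistic-calibrated so that scores
>= 0.5 mean disordered.
"""
import numpy as np

from scestruct import predictors, report

rng = np.random.default_rng(3)
background = "".join(rng.choice(list(predictors.AMINO_ACIDS), size=60))
sequence = background[:25] + "SPEKSPEKSPEKSPEK" + background[25:]

lc = predictors.low_complexity_mask(sequence)
scores = predictors.disorder_scores(sequence)
print(f"sequence length: {len(sequence)}")
print(f"low-complexity residues: {int(lc.sum())} "
      f"(the planted SPEK repeat drops the window entropy below 2.2 bits)")
print(f"residues scoring >= 0.5 disorder: {int((scores >= 0.5).sum())} "
      f"(disorder-promoting S/P/E/K composition raises the score)")

annotation = predictors.build_annotation("demo", sequence, disorder=scores)
print()
print(report.protein_report("demo", sequence, annotation), end="")
# 'L' marks low-complexity residues, 'D' disordered ones; the two tracks are
# computed independently, mirroring SEG and IUPred on real data.
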