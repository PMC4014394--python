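"""The core analysis: SCE-encoded segments vs length-matched references.

Runs the full simulate -> map -> annotate -> measure -> compare pass and
prints, per detection window and structural property, the fraction of
>= 50%-assigned segments in both groups with the Yates chi-square and
Mann-Whitney p-values, then the window-size trend (Spearman correlation of
the descriptive values with window size, plus Kruskal-Wallis/Dunn tests).
"""
from scestruct.enrichment_pipelines import run_synthetic_end_to_end
from scestruct.synthetic_data import SyntheticConfig
from scestruct.types import PROPERTIES

run = run_synthetic_end_to_end(
    SyntheticConfig(delta0=0.5, n_genes=300, seed=1), analysis_seed=1
)

threshold = run.comparison.metadata["bonferroni_threshold"]
print(f"Bonferroni-corrected significance threshold: {threshold}")
for w in sorted(run.comparison.tests):
    print(f"\n-- {w}-codon resolution "
          f"({run.comparison.counts[w]['n_sce']} segments) --")
    for prop in PROPERTIES:
        t = run.comparison.tests[w][prop]
        cmp_ = run.comparison.tables[w][prop]
        arrow = "enriched" if t["direction"] > 0 else "depleted"
        star = "*" if t["significant"] else " "
        print(f"  {prop:20s} SCE {cmp_.test_rate:5.1%} vs ref {cmp_.ref_rate:5.1%}"
              f"  chi2 p={t['chi_square'].p_value:.2e}"
              f"  MWU p={t['mann_whitney'].p_value:.2e}  {arrow}{star}")

print("\nwindow-size trend (descriptive value vs window size):")
for prop, rho in run.trend.correlations.items():
    vals = run.trend.descriptives[prop]
    shown = ", ".join(f"{w}: {v:.3f}" for w, v in vals.items())
    print(f"  {prop:20s} rho = {rho:+.3f}   ({shown})")
# Disorder and low complexity fall, secondary structure rises with window
# size: the planted effect weakens as the window grows (delta ~ 9/w), the
# pattern the analysis is designed to detect.
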