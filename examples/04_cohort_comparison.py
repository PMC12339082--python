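"""A two-genotype cohort from simulation to group statistics.

Simulates a small wild-type/mutant cohort with a planted growth-plate
thinning (-25%), writes it to disk as TIFFs plus a manifest, runs the whole
measurement pipeline over the manifest, and prints the normality-gated
group comparisons.
"""

import tempfile
from pathlib import Path

from osteoquant import RunConfig, generate_cohort, run_cohort
from osteoquant.synthetic import SyntheticConfig

cfg = SyntheticConfig(image_width_px=520, metaphysis_um=700.0, epiphysis_um=200.0)
cohort = generate_cohort(
    cfg, n_wt=5, n_mut=5, seed=11,
    effects={"growth_plate_thickness": 0.75},  # mutant growth plate 25% thinner
    age_group="8W",
)

with tempfile.TemporaryDirectory() as tmp:
    manifest = cohort.write(Path(tmp) / "cohort")
    # short secondary band to match the compact phantom geometry
    report = run_cohort(manifest, RunConfig(secondary_band_um=150.0))

cols = ["measure", "test", "p_value", "mean_wt", "mean_mut", "percent_difference"]
print(report.comparisons[cols].round(3).to_string(index=False))
print(f"\nreference BMDD percentiles: p5 = {report.reference_p5:.2f}, "
      f"p95 = {report.reference_p95:.2f} wt%Ca")

# The growth-plate row shows a percent difference near the planted -25%
# with p < 0.05, while measures without a planted effect stay flat.
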