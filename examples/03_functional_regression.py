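"""Two-group functional regression on a full synthetic cohort.

Extracts kinematic profiles for 18 + 18 subjects, represents each signal as
a GCV-selected penalized B-spline function, and fits the function-on-scalar
model y_i(t) = beta_ref(t) + Z_i * beta_diff(t) + eps_i(t) per signal.
Percentile intervals where the pointwise 95% band of beta_diff excludes
zero are the time windows of significant group difference.
"""

from hyoidkin import SyntheticCohortConfig, generate_cohort
from hyoidkin.pipeline import analyze_cohort, extract_cohort

cfg = SyntheticCohortConfig()
series, truths, labels = generate_cohort(cfg, seed=1)
profiles, summaries = extract_cohort(series, cfg.calibration)

analysis = analyze_cohort(profiles, labels, summaries=summaries)

for signal, fit in analysis.fits.items():
    ch = analysis.smoothing[signal]
    ivals = ", ".join(f"[{lo:.0f}, {hi:.0f}]" for lo, hi in fit.intervals) or "none"
    print(f"{signal:7s} K={ch.n_basis:2d} lambda={ch.lam:8g} df={ch.df:5.2f}  "
          f"significant percentiles: {ivals}")

# beta_diff estimates (poor - good) at each normalized time point; for
# horizontal displacement a negative mid-swallow interval marks the reduced
# forward excursion of the poor-prognosis group.
fit = analysis.fits["disp_x"]
mid = fit.grid[50]
print(f"\nbeta_diff(disp_x) at percentile {mid:.0f}: {fit.beta_diff[50]:.2f} mm "
      f"(95% CI {fit.lower[50]:.2f} .. {fit.upper[50]:.2f})")
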