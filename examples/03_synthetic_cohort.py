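"""Generate a paired tumour/normal cohort and run the full analysis.

Uses the single-patient design (9 tumour / 3 normal biopsies, target RSI
0.43 vs 0.52) and prints the group summaries and Welch comparison the
pipeline recovers from raw synthetic counts.
"""

from radsens import (
    breast_design,
    build_report,
    generate_cohort,
    profile_sample,
    resolve_panel,
    tmm_normalize,
)

cfg = breast_design(seed=42)
cm, sheet, truth = generate_cohort(cfg)
print(f"generated {cm.n_genes} genes x {cm.n_samples} samples, regimen {cfg.regimen}")

nm = tmm_normalize(cm)
panel_map = resolve_panel(cm)
profiles = [
    profile_sample(nm, panel_map, sid, cfg.regimen) for sid in cm.sample_ids
]
report = build_report(
    profiles,
    {sid: sheet.tissue_of(sid) for sid in cm.sample_ids},
)

for s in report.summaries:
    print(f"{s.label:>6} {s.metric:>4}: {s.mean:.3f} +/- {s.sd:.3f}  (n={s.n_samples})")
for metric, w in report.welch.items():
    print(
        f"Welch {metric}: t={w.t_statistic:.3f}, "
        f"df={w.degrees_of_freedom:.2f}, p={w.p_value:.4f}"
    )
print(f"GARD-high threshold (tumour median): {report.gard_high_threshold:.2f}")

# The recovered group means should sit near the generator targets (0.43 /
# 0.52); tumour GARD exceeds normal GARD because GARD decreases in RSI.
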