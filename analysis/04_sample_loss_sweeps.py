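"""Sample-loss robustness sweeps (distributed and consecutive).

Shortens every cohort signal by a fraction eta of its samples — either
scattered individual samples or one contiguous block — over the study's
eta grid. Distributed removal whitens the record, so SampEn rises
roughly linearly with eta; consecutive removal preserves the surviving
statistics, so SampEn stays near baseline. Both sweeps report the class
separation and the baseline correlation at every level.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import egmentropy as eg
from egmentropy.io import StudyConfig, write_report
from study_setup import MASTER_SEED, N_REALISATIONS, RESULTS, calibrated_spec


def main() -> None:
    spec, _ = calibrated_spec(MASTER_SEED)
    cohort = eg.generate_cohort(spec)
    cfg = StudyConfig(cohort=spec, master_seed=MASTER_SEED,
                      n_realisations=N_REALISATIONS)
    RESULTS.mkdir(exist_ok=True)

    for kind in ("loss_distributed", "loss_consecutive"):
        report = eg.run_sweep(
            cohort, kind, n_realisations=N_REALISATIONS, master_seed=MASTER_SEED
        )
        write_report(report, RESULTS / kind, cfg)
        print(f"\n{kind}:")
        for label in ("NC", "C"):
            means = report.class_means(label)
            drift = 100.0 * np.max(np.abs(means / means[0] - 1.0))
            fit = report.linear_fit[label]
            print(f"  {label}: mean {means[0]:.3f} -> {means[-1]:.3f} over eta grid "
                  f"(max drift {drift:.1f}%)")
            print(f"      linear fit f(eta%) = {fit.slope:.4g}*eta + "
                  f"{fit.intercept:.3f}, R^2 = {fit.r_squared:.3f}, "
                  f"resid. SE = {fit.std_error_pct:.2f}% of mean")
        worst_p = max(ls.p_value for ls in report.levels)
        worst_rho = min(ls.rho_xy for ls in report.levels)
        print(f"  separation p <= {worst_p:.2e} at every level; "
              f"rho_xy >= {worst_rho:.3f} (robust at all levels: "
              f"{all(ls.robust for ls in report.levels)})")
        print(f"  ROC AUC at eta=10%: {report.roc[0.10].auc:.3f}")


if __name__ == "__main__":
    main()
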