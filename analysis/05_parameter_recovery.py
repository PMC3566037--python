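"""Multi-seed parameter recovery against the closed-form oracle.

Generates 20 default cohorts (n = 3,000/sex), runs the full pipeline, fits
the systolic growth models, and compares the seed-averaged coefficients
with the implied (covariance-algebra) values — the quantitative version of
the reversal pattern: marginal CWV 0.40/0.44, marginal birth weight
0.00/0.03, conditional birth weight -0.10/-0.09, conditional CWV 0.
"""

from pathlib import Path

from capload.experiments import growth_model_fits, summarize_recovery
from capload.simulate import calibrate_default_config, implied_coefficients

OUT = Path(__file__).resolve().parents[1] / "results"
SEEDS = range(20)


def main():
    config = calibrate_default_config(n={"male": 3000, "female": 3000})
    implied = {}
    for sex in ("male", "female"):
        for model, name in (("model2", "marginal_growth"), ("model3", "joint_full")):
            for term, val in implied_coefficients(config, name, sex).items():
                implied[(model, sex, term)] = val

    fits = growth_model_fits(config, SEEDS)
    summary = summarize_recovery(fits, implied)
    summary.to_csv(OUT / "parameter_recovery.csv", index=False)

    growth = summary[summary.term.isin(["bwz", "cwv"])]
    print("growth-coefficient recovery over 20 seeds (derived pipeline):")
    for _, r in growth.iterrows():
        print(f"  {r['model']} {r['sex']:6s} {r['term']:4s} "
              f"mean {r['mean_beta']:+.3f}  implied {r['implied']:+.3f}  "
              f"bias {r['bias']:+.4f}  sem {r['sem']:.4f}")
    print(f"\nfull summary written to {OUT / 'parameter_recovery.csv'}")


if __name__ == "__main__":
    main()
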