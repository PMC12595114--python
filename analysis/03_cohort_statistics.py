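#!/usr/bin/env python
"""Cohort statistics on the quantified phantom mice.

Reads the per-mouse records written by 02_quantify_cohort.py and reports the
cohort-level quantities the pipeline is built for: per-BP biomass fractions
and Shannon diversity, mono/polychromatic proportions, per-mouse medians of
the vessel metrics with the paired mono-vs-poly test, the IV-vs-MFP
independent test, and a null-preset calibration of the paired test. Writes
results/cohort/statistics.json and a summary figure.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kstest

from lobemap.cohort import null_pvalues
from lobemap.io import read_records
from lobemap.stats import (
    count_fractions,
    independent_t_test,
    mono_poly_summary,
    paired_t_test,
    per_mouse_median,
    shannon_diversity,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--null-runs", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    record_files = sorted(args.cohort_dir.glob("records_*.csv"))
    if not record_files:
        raise SystemExit(f"no records in {args.cohort_dir}; run 02_quantify_cohort.py first")
    records = [r for p in record_files for r in read_records(p)]
    print(f"loaded {len(records)} metastases from {len(record_files)} mice")

    out: dict = {}

    # BP diversity (by metastasis counts, pooled across the cohort)
    fractions = count_fractions(records)
    out["bp_count_fractions"] = {str(k): v for k, v in fractions.items()}
    out["shannon_counts_nats"] = shannon_diversity(list(fractions.values()))
    print(f"Shannon diversity over BP counts: {out['shannon_counts_nats']:.3f} nats "
          f"(maximum ln 7 = {np.log(7):.3f})")

    # mono/poly proportions per mouse
    mp = mono_poly_summary(records)
    out["mono_poly_per_mouse"] = mp.to_dict(orient="records")
    print(f"mean monochromatic proportion: {mp['proportion_mono'].mean():.2f}")

    # per-mouse medians + paired mono-vs-poly tests
    tests = {}
    for metric in ("normalized_distance", "nearest_vessel_diameter_um", "contact_area_um2"):
        med = per_mouse_median(records, metric)
        wide = med.pivot_table(index=["mouse_id", "group"], columns="chromatic_class",
                               values="value").reset_index()
        paired = wide.dropna(subset=["monochromatic", "polychromatic"])
        res = paired_t_test(paired["monochromatic"], paired["polychromatic"])
        tests[metric] = {"t": res.t, "p": res.p, "n_mice": res.n, "degenerate": res.degenerate}
        note = "  [degenerate: zero-variance differences]" if res.degenerate else ""
        print(f"paired t (mono vs poly) on median {metric}: "
              f"t = {res.t:.2f}, p = {res.p:.2e}, n = {res.n} mice{note}")
    out["paired_tests_mono_vs_poly"] = tests

    # IV vs MFP independent test on per-mouse normalized distance medians
    med = per_mouse_median(records, "normalized_distance", by_class=False)
    iv = med[med["group"] == "IV"]["value"].to_numpy()
    mfp = med[med["group"] == "MFP"]["value"].to_numpy()
    res = independent_t_test(iv, mfp)
    out["independent_test_iv_vs_mfp"] = {"t": res.t, "p": res.p, "n_iv": res.n, "n_mfp": res.n2}
    print(f"independent t (IV vs MFP) on median normalized distance: "
          f"t = {res.t:.2f}, p = {res.p:.3f}")

    # null calibration: same test under the no-effect preset
    seeds = [(args.seed * 1009 + i) % (2**31 - 1) for i in range(args.null_runs)]
    ps = null_pvalues(seeds)
    ks = kstest(ps, "uniform")
    out["null_calibration"] = {"n_runs": len(ps), "ks_p": ks.pvalue, "mean_p": float(np.mean(ps))}
    print(f"null preset over {len(ps)} cohorts: mean p = {np.mean(ps):.2f}, "
          f"KS uniformity p = {ks.pvalue:.3f}")

    (args.cohort_dir / "statistics.json").write_text(json.dumps(out, indent=2, default=float))

    # summary figure: paired medians + null p-value histogram
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        med = per_mouse_median(records, "normalized_distance")
        wide = med.pivot_table(index="mouse_id", columns="chromatic_class", values="value")
        for _, row in wide.iterrows():
            axes[0].plot([0, 1], [row["monochromatic"], row["polychromatic"]],
                         "o-", color="grey", alpha=0.7)
        axes[0].set_xticks([0, 1], ["monochromatic", "polychromatic"])
        axes[0].set_ylabel("median distance / equivalent radius")
        axes[0].set_title("per-mouse vessel proximity by class")
        axes[1].hist(ps, bins=20, range=(0, 1), color="steelblue", edgecolor="white")
        axes[1].set_xlabel("p-value under the null preset")
        axes[1].set_title(f"null calibration ({len(ps)} cohorts)")
        fig.tight_layout()
        fig.savefig(args.cohort_dir / "cohort_statistics.png", dpi=150)
        print(f"figure written to {args.cohort_dir / 'cohort_statistics.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
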