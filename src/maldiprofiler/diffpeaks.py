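"""Differential-peak statistics between the two classes.

Per picked peak: AUROC via the Mann-Whitney rank-sum identity, log2 fold
change of class means with a Welch unpaired t-test (volcano coordinates),
and Benjamini-Hochberg adjustment across peaks. ``butterfly_means`` prepares
the mirrored mean-spectra comparison payload.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peaks import PeakMatrix


@dataclass
class DiffPeakResult:
    mz: float
    log2_fc: float  # mean(LGP) / mean(FA), log2
    t_stat: float
    p_value: float
    p_adjusted: float
    auroc: float  # P(LGP intensity > FA intensity) + half ties
    flags: tuple = ()


def peak_auroc(intensities_a: np.ndarray, intensities_b: np.ndarray) -> float:
    """AUROC = P(random b > random a) + 0.5 * P(tie).

    Computed through the rank-sum identity AUROC = U_b / (n_a * n_b) with
    midranks for ties; identical to the normalized Mann-Whitney U statistic.
    """
    a = np.asarray(intensities_a, dtype=float)
    b = np.asarray(intensities_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    rank_sum_b = ranks[len(a):].sum()
    u_b = rank_sum_b - len(b) * (len(b) + 1) / 2.0
    return float(u_b / (len(a) * len(b)))


def volcano_stats(
    matrix: PeakMatrix,
    labels: np.ndarray | None = None,
    fc_line: float = 1.0,
    p_line: float = 0.05,
    group_a: str = "FA",
    group_b: str = "LGP",
    unit: str = "spot",
    equal_var: bool = False,
) -> dict:
    """Volcano coordinates per peak: log2 FC (``group_b`` over ``group_a``),
    Welch unpaired t statistic with two-sided p, BH-adjusted p, and AUROC.

    ``unit='case'`` first averages spots within each case so cases, not
    spots, are the replicates (spot-level tests are pseudo-replicated under
    case heterogeneity). ``equal_var=True`` switches to the pooled-variance
    t-test. Returns the result list plus counts of peaks past the fold-change
    and p-value guide lines.
    """
    labels = np.asarray(labels if labels is not None else matrix.meta["class_label"])
    values = matrix.values
    if unit == "case":
        cases = matrix.meta["case_id"].to_numpy()
        uniq = list(dict.fromkeys(cases))
        values = np.vstack([values[cases == c].mean(axis=0) for c in uniq])
        labels = np.array([labels[cases == c][0] for c in uniq])
    elif unit != "spot":
        raise ValueError("unit must be 'spot' or 'case'")

    mask_a, mask_b = labels == group_a, labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"need >= 2 replicates per class; got {mask_a.sum()} {group_a}, {mask_b.sum()} {group_b}")
    A, B = values[mask_a], values[mask_b]

    eps = np.finfo(float).eps
    results = []
    raw_p = np.ones(len(matrix.mz))
    for j, mz in enumerate(matrix.mz):
        a, b = A[:, j], B[:, j]
        flags = []
        ma, mb = a.mean(), b.mean()
        if ma <= eps or mb <= eps:
            flags.append("zero_mean_floored")
        fc = np.log2(max(mb, eps) / max(ma, eps))
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = 0.0, 1.0
            flags.append("zero_variance")
        else:
            t, p = stats.ttest_ind(b, a, equal_var=equal_var)
            if np.isnan(p):
                t, p = 0.0, 1.0
                flags.append("undefined_t")
        raw_p[j] = p
        results.append(
            DiffPeakResult(
                mz=float(mz),
                log2_fc=float(fc),
                t_stat=float(t),
                p_value=float(p),
                p_adjusted=1.0,  # filled below
                auroc=peak_auroc(a, b),
                flags=tuple(flags),
            )
        )
    if results:
        adj = multipletests(raw_p, method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    n_past_fc = sum(abs(r.log2_fc) >= fc_line for r in results)
    n_past_both = sum(
        abs(r.log2_fc) >= fc_line and r.p_value < p_line for r in results
    )
    return {
        "results": results,
        "n_peaks": len(results),
        "n_past_fc_line": n_past_fc,
        "n_significant_raw": int(np.sum(raw_p < p_line)),
        "n_past_both": n_past_both,
        "fc_line": fc_line,
        "p_line": p_line,
        "unit": unit,
    }


def butterfly_means(spectra_by_class: dict, flip: str = "LGP") -> dict:
    """Mirrored mean-profile comparison of two classes.

    Returns the mean profile of each class on the common axis, with the
    ``flip`` class negated for back-to-back plotting, plus the absolute
    difference profile. Plotting payload only.
    """
    from .peaks import mean_spectrum

    if len(spectra_by_class) != 2:
        raise ValueError("butterfly_means needs exactly two classes")
    (name_a, specs_a), (name_b, specs_b) = sorted(spectra_by_class.items())
    mean_a = mean_spectrum(specs_a)
    mean_b = mean_spectrum(specs_b)
    profile_a, profile_b = mean_a.intensity, mean_b.intensity
    return {
        "mz": mean_a.mz,
        name_a: profile_a if name_a != flip else -profile_a,
        name_b: profile_b if name_b != flip else -profile_b,
        "abs_difference": np.abs(profile_a - profile_b),
    }


def volcano_table(volcano: dict):
    """Flatten a volcano_stats result into a DataFrame for delimited output."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mz": r.mz,
                "log2_fc": r.log2_fc,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "auroc": r.auroc,
                "flags": ";".join(r.flags),
            }
            for r in volcano["results"]
        ]
    )


def volcano_plot(volcano: dict, path) -> None:
    """Write a volcano plot (log2 FC vs -log10 p) with guide lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fc = np.array([r.log2_fc for r in volcano["results"]])
    p = np.array([r.p_value for r in volcano["results"]])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fc, -np.log10(np.maximum(p, 1e-300)), s=8, c="black")
    ax.axhline(-np.log10(volcano["p_line"]), color="red", ls=":")
    for x in (-volcano["fc_line"], volcano["fc_line"]):
        ax.axvline(x, color="black", ls=":")
    ax.set_xlabel("log2 fold change (LGP / FA)")
    ax.set_ylabel("-log10 p (unpaired t-test)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
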