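"""Guide-level enrichment: RPM normalization, log2 fold change, p-values.

Counts are normalized to reads-per-million (RPM) per sample; for
fixed-length guide cassettes a per-kilobase normalization differs from RPM
only by a constant that cancels in fold change, so RPM is the statistic
computed throughout, and ``log2(RPM + c)`` is exposed as the "transformed"
abundance for reporting. Replicates are combined by averaging RPM within
timepoint before the fold change (per-replicate fold changes are emitted
alongside for intersection-style analyses).

Three one-sided (enrichment) p-value methods are provided:

``robust_z``
    z-score of each guide's log2FC against the median/MAD of all guides,
    upper normal tail. Default: with two replicates an explicit replicate
    test is underpowered, while the bulk of a genome-scale library is a
    good empirical null.
``control_null``
    Empirical upper-tail probability against the non-targeting-control
    fold-change distribution, with add-one smoothing.
``permutation``
    Timepoint-label permutation of the replicate columns; empirical upper
    tail over all (or sampled) label assignments. Because each replicate's
    day-0 and day-14 samples are paired (the same infected pool sequenced
    before and after selection), labels are exchanged within replicates —
    the permutation scheme that respects the pairing. With R replicates
    there are 2^R assignments, so attainable p-values are multiples of
    2^-R; a meaningful test at alpha = 0.05 needs R >= 5.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .library import CONTROL_LABEL, SgRNALibrary
from .simulate import parse_sample

DEFAULT_PSEUDOCOUNT = 1.0

P_VALUE_METHODS = ("robust_z", "control_null", "permutation")


def normalize_rpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Scale each sample (column) to reads-per-million."""
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            name = counts.name or "<sample>"
            raise ValueError(f"sample {name!r} has zero total reads")
        return counts / total * 1e6
    out = {}
    for col in counts.columns:
        total = counts[col].sum()
        if total <= 0:
            raise ValueError(f"sample {col!r} has zero total reads")
        out[col] = counts[col] / total * 1e6
    return pd.DataFrame(out, index=counts.index)


def log2fc(rpm_t14, rpm_t0, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """``log2((rpm_t14 + c) / (rpm_t0 + c))``; the pseudocount guards zeros."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = np.asarray(rpm_t14, dtype=float)
    b = np.asarray(rpm_t0, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("RPM values must be non-negative")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return float(out) if out.ndim == 0 else out


def transformed_rpm(rpm, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Reporting transform ``log2(RPM + c)``."""
    return np.log2(np.asarray(rpm, dtype=float) + pseudocount)


def _fc_from_counts(
    counts: pd.DataFrame,
    t0_cols: list[str],
    t14_cols: list[str],
    pseudocount: float,
) -> np.ndarray:
    rpm = normalize_rpm(counts[t0_cols + t14_cols])
    return log2fc(
        rpm[t14_cols].mean(axis=1), rpm[t0_cols].mean(axis=1), pseudocount
    )


def sgrna_pvalues(
    fc: np.ndarray,
    method: str = "robust_z",
    *,
    is_control: np.ndarray | None = None,
    counts: pd.DataFrame | None = None,
    t0_cols: list[str] | None = None,
    t14_cols: list[str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_exact_permutations: int = 1000,
    n_permutations: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """One-sided enrichment p-value per guide for the given log2FCs."""
    fc = np.asarray(fc, dtype=float)
    if method == "robust_z":
        if fc.size < 50:
            raise ValueError("robust_z needs >= 50 guides for a stable null")
        med = np.median(fc)
        mad = np.median(np.abs(fc - med))
        if mad == 0:
            raise ValueError("robust_z: MAD is zero (degenerate fold-change distribution)")
        z = (fc - med) / (1.4826 * mad)
        return stats.norm.sf(z)

    if method == "control_null":
        if is_control is None or not np.asarray(is_control).any():
            raise ValueError("control_null requires non-targeting controls")
        ctrl = np.sort(fc[np.asarray(is_control, dtype=bool)])
        n_ctrl = ctrl.size
        # count of controls >= fc_i, via searchsorted on the sorted null
        n_ge = n_ctrl - np.searchsorted(ctrl, fc, side="left")
        return (1.0 + n_ge) / (n_ctrl + 1.0)

    if method == "permutation":
        if counts is None or t0_cols is None or t14_cols is None:
            raise ValueError("permutation requires counts and column groups")
        if len(t0_cols) != len(t14_cols):
            raise ValueError("permutation requires paired timepoint groups")
        pairs = list(zip(t0_cols, t14_cols))
        r = len(pairs)
        if 2**r <= max_exact_permutations:
            flips = [
                [i in chosen for i in range(r)]
                for size in range(r + 1)
                for chosen in combinations(range(r), size)
            ]
        else:
            rng = np.random.default_rng(seed)
            flips = [[False] * r]  # observed labelling first
            flips += (rng.random((n_permutations, r)) < 0.5).tolist()
        n_ge = np.zeros(fc.size)
        for flip in flips:
            p0 = [t14 if f else t0 for (t0, t14), f in zip(pairs, flip)]
            p14 = [t0 if f else t14 for (t0, t14), f in zip(pairs, flip)]
            perm_fc = _fc_from_counts(counts, p0, p14, pseudocount)
            n_ge += perm_fc >= fc - 1e-12
        return n_ge / len(flips)

    raise ValueError(f"unknown p-value method {method!r}")


def gene_group_test(values) -> tuple[float, float]:
    """One-sample t and Wilcoxon signed-rank of a gene's guide log2FCs vs 0.

    Both tests are two-sided, summarizing whether a gene's guides are
    collectively displaced from no change. Degenerate inputs: all-zero
    values return p = 1 for both tests (no displacement, no ranks); a
    nonzero constant has an undefined t statistic and is flagged with
    t_p = 0 (infinite evidence of displacement under the model).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise ValueError("gene_group_test needs at least one value")
    if np.all(vals == 0):
        return 1.0, 1.0

    if vals.size < 2:
        t_p = float("nan")
    elif np.ptp(vals) == 0:
        t_p = 0.0
    else:
        t_p = float(stats.ttest_1samp(vals, 0.0).pvalue)

    nonzero = vals[vals != 0]
    if nonzero.size == 0:
        w_p = 1.0
    else:
        w_p = float(stats.wilcoxon(nonzero).pvalue)
    return t_p, w_p


def enrichment_table(
    counts: pd.DataFrame,
    lib: SgRNALibrary,
    arm: str = "drug",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "robust_z",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-guide enrichment between day 0 and day 14 of one arm.

    Returns a frame indexed by sgrna_id with columns gene, rpm_t0, rpm_t14
    (replicate means), per-replicate log2FCs, log2fc, p_value and the two
    filter flags, sorted by descending log2fc.
    """
    if fc_threshold <= 0 or not (0 < alpha < 1):
        raise ValueError("thresholds must be positive (0 < alpha < 1)")
    groups: dict[tuple[str, str], list[str]] = {}
    for col in counts.columns:
        a, tp, _ = parse_sample(col)
        groups.setdefault((a, tp), []).append(col)
    t0_cols = sorted(groups.get((arm, "day0"), []))
    t14_cols = sorted(groups.get((arm, "day14"), []))
    if not t0_cols or not t14_cols:
        raise ValueError(f"counts lack day0/day14 samples for arm {arm!r}")

    missing = set(lib.sgrna_ids) ^ set(counts.index)
    if missing:
        raise ValueError(f"counts and library disagree on guides: {sorted(missing)[:3]}")
    counts = counts.loc[lib.sgrna_ids]

    rpm = normalize_rpm(counts[t0_cols + t14_cols])
    rpm_t0 = rpm[t0_cols].mean(axis=1)
    rpm_t14 = rpm[t14_cols].mean(axis=1)
    fc = log2fc(rpm_t14, rpm_t0, pseudocount)

    gene_of = lib.gene_of()
    is_control = np.array([gene_of[sg] == CONTROL_LABEL for sg in counts.index])
    pvals = sgrna_pvalues(
        fc,
        method,
        is_control=is_control,
        counts=counts,
        t0_cols=t0_cols,
        t14_cols=t14_cols,
        pseudocount=pseudocount,
        seed=seed,
    )

    out = pd.DataFrame(
        {
            "gene": [gene_of[sg] for sg in counts.index],
            "rpm_t0": rpm_t0,
            "rpm_t14": rpm_t14,
            "log2fc": fc,
            "p_value": pvals,
            "passes_fc": fc >= fc_threshold,
            "passes_p": pvals < alpha,
        },
        index=counts.index,
    )
    for k, (c0, c14) in enumerate(zip(t0_cols, t14_cols), start=1):
        out[f"log2fc_rep{k}"] = log2fc(rpm[c14], rpm[c0], pseudocount)
    out.attrs.update(fc_threshold=fc_threshold, alpha=alpha, method=method)
    return out.sort_values("log2fc", ascending=False)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sgrna_id")


def read_enrichment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sgrna_id")
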