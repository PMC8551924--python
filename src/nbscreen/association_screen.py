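"""All-pairs gene-drug association screen.

For every gene x drug pair, the Pearson correlation r between the gene's copy
number (log2 ratio by default) and the drug's normalized cytotoxicity across
samples is transformed to Fisher's z = atanh(r) (reported, with its
standardized form z * sqrt(n - 3)); per-pair p-values default to the exact
small-sample test t = r * sqrt(n-2) / sqrt(1-r^2) on n-2 df, because the
normal tail of the standardized Fisher statistic is anticonservative in the
deep tail at n ~ 13 (set ``test="normal"`` for the large-sample convention).
P-values are adjusted with the Benjamini-Hochberg step-up procedure at FDR
q = 0.1. Significant pairs are
cross-classified against the drug library's expected targets (TP/FP/FN/TN) and
ranked by the product of the drug's mean cytotoxicity and the pair's z.

Pairs whose copy-number or cytotoxicity vector is constant (or has too few
paired observations) are undefined: they are excluded from the multiplicity
count m rather than assigned p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from scipy import stats

from .drug_screen import CytotoxicityMatrix
from .genomic_profiling import CopyNumberProfile

__all__ = [
    "ScreenConfig",
    "ScreenInputError",
    "pearson_r",
    "fisher_z",
    "pair_pvalue",
    "bh_fdr",
    "run_screen",
    "classify_against_expected",
    "rank_by_effect",
    "verify_against_annotation_sets",
]

_CLAMP = 1.0 - 1e-7
_VAR_EPS = 1e-24


class ScreenInputError(ValueError):
    """Invalid screen input (no shared samples, malformed tables)."""


@dataclass(frozen=True)
class ScreenConfig:
    fdr_threshold: float = 0.1
    min_samples: int = 5
    use_log2: bool = True  # correlate log2 ratios (False: absolute copies)
    two_sided: bool = True
    test: str = "exact"  # "exact": t on n-2 df; "normal": z*sqrt(n-3) vs N(0,1)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ScreenInputError("fdr_threshold must be in (0, 1)")
        if self.min_samples < 4:
            raise ScreenInputError("min_samples must be >= 4 (z test needs n > 3)")
        if self.test not in ("exact", "normal"):
            raise ScreenInputError("test must be 'exact' or 'normal'")


def pearson_r(x, y) -> float:
    """Product-moment correlation on paired finite observations.

    Raises on constant vectors -- such pairs are 'undefined' in the screen,
    not zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ScreenInputError("need at least two paired observations")
    if np.var(x) <= _VAR_EPS or np.var(y) <= _VAR_EPS:
        raise ScreenInputError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher variance-stabilizing transform z = atanh(r).

    |r| = 1 is clamped to 1 - 1e-7 with a warning so planted perfect
    correlations stay finite.
    """
    r = float(r)
    if not -1.0 <= r <= 1.0:
        raise ScreenInputError(f"|r| must be <= 1, got {r}")
    if abs(r) > _CLAMP:
        warnings.warn("|r| at or near 1; clamping before atanh", stacklevel=2)
        r = np.sign(r) * _CLAMP
    return float(np.arctanh(r))


def pair_pvalue(z: float, n: int, two_sided: bool = True) -> tuple[float, float]:
    """Standardize z by sqrt(n-3) and return (z_std, normal-tail p)."""
    if n < 4:
        raise ScreenInputError("p-value undefined for n < 4")
    z_std = float(z) * np.sqrt(n - 3)
    if two_sided:
        p = 2.0 * stats.norm.sf(abs(z_std))
    else:
        p = stats.norm.sf(z_std)
    return z_std, float(min(p, 1.0))


def bh_fdr(pvalues, q_threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted q per p, rejection flags).

    Classic step-up: reject hypotheses 1..k where k = max{i: p(i) <= i*q/m};
    adjusted values are the monotone cumulative-min form.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ScreenInputError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return qvals, reject


def _matrix(values, use_log2: bool = True) -> pd.DataFrame:
    if isinstance(values, CopyNumberProfile):
        return values.log2_ratio if use_log2 else values.copies
    if isinstance(values, CytotoxicityMatrix):
        return values.values
    return values


def run_screen(
    cnv, cytotoxicity, config: ScreenConfig = ScreenConfig()
) -> pd.DataFrame:
    """All-pairs correlation screen.

    Accepts a CopyNumberProfile (or gene x sample frame) and a
    CytotoxicityMatrix (or drug x sample frame). Returns one row per
    enumerated gene x drug pair with columns: gene_id, drug_id, n, r, z,
    z_std, p, q, significant, testable, reason. Undefined pairs keep NaN
    statistics and a reason ('constant' or 'too_few_samples'); BH multiplicity
    m counts testable pairs only.
    """
    G = _matrix(cnv, config.use_log2)
    D = _matrix(cytotoxicity)
    shared = [s for s in G.columns if s in set(D.columns)]
    if not shared:
        raise ScreenInputError("no shared samples between CNV and cytotoxicity matrices")
    X = G[shared].to_numpy(dtype=float)  # genes x S
    Y = D[shared].to_numpy(dtype=float)  # drugs x S
    genes = list(G.index)
    drugs = list(D.index)
    n_genes, n_drugs = len(genes), len(drugs)

    Xf = np.isfinite(X)
    X0 = np.where(Xf, X, 0.0)

    r_mat = np.full((n_genes, n_drugs), np.nan)
    n_mat = np.zeros((n_genes, n_drugs), dtype=int)
    reason = np.full((n_genes, n_drugs), "", dtype=object)

    for j in range(n_drugs):
        y = Y[j]
        yf = np.isfinite(y)
        M = Xf & yf  # genes x S pairwise-complete mask
        n = M.sum(axis=1)
        n_mat[:, j] = n
        y0 = np.where(yf, y, 0.0)
        sx = (X0 * M).sum(axis=1)
        sy = M @ y0
        sxx = (X0**2 * M).sum(axis=1)
        syy = M @ (y0**2)
        sxy = (X0 * M) @ y0
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = n.astype(float)
            cov = sxy - sx * sy / np.where(nn > 0, nn, np.nan)
            vx = sxx - sx**2 / nn
            vy = syy - sy**2 / nn
            r = cov / np.sqrt(vx * vy)
        low_n = n < config.min_samples
        const = (~low_n) & ((vx <= _VAR_EPS * nn) | (vy <= _VAR_EPS * nn))
        ok = ~(low_n | const)
        r_mat[ok, j] = np.clip(r[ok], -1.0, 1.0)
        reason[low_n, j] = "too_few_samples"
        reason[const, j] = "constant"

    table = pd.DataFrame(
        {
            "gene_id": np.repeat(genes, n_drugs),
            "drug_id": np.tile(drugs, n_genes),
            "n": n_mat.ravel(),
            "r": r_mat.ravel(),
            "reason": reason.ravel(),
        }
    )
    table["testable"] = table["r"].notna() & (table["n"] >= 4)
    table.loc[table["r"].notna() & (table["n"] < 4), "reason"] = "too_few_samples"
    table.loc[table["r"].notna() & (table["n"] < 4), "r"] = np.nan
    table.loc[~table["testable"] & (table["reason"] == ""), "reason"] = "constant"

    rt = table.loc[table["testable"], "r"].to_numpy()
    clamped = np.abs(rt) > _CLAMP
    rc = np.where(clamped, np.sign(rt) * _CLAMP, rt)
    zt = np.arctanh(rc)
    nt = table.loc[table["testable"], "n"].to_numpy()
    z_std = zt * np.sqrt(nt - 3)
    if config.test == "normal":
        stat = z_std
        sf = stats.norm.sf(np.abs(stat))
        sf_signed = stats.norm.sf(stat)
    else:
        stat = rc * np.sqrt(nt - 2) / np.sqrt(1.0 - rc**2)
        sf = stats.t.sf(np.abs(stat), nt - 2)
        sf_signed = stats.t.sf(stat, nt - 2)
    pt = np.minimum(2.0 * sf if config.two_sided else sf_signed, 1.0)
    qt, reject = bh_fdr(pt, config.fdr_threshold)

    for col in ("z", "z_std", "p", "q"):
        table[col] = np.nan
    table.loc[table["testable"], "z"] = zt
    table.loc[table["testable"], "z_std"] = z_std
    table.loc[table["testable"], "p"] = pt
    table.loc[table["testable"], "q"] = qt
    table["significant"] = False
    table.loc[table["testable"], "significant"] = reject
    table["clamped"] = False
    table.loc[table["testable"], "clamped"] = clamped
    return table


def classify_against_expected(
    table: pd.DataFrame, expected: Iterable[tuple[str, str]]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Add expected/venn_class columns; return (table, venn counts).

    TP = significant & expected, FP = significant & unexpected,
    FN = expected & not significant, TN = neither. Counts always sum to the
    number of enumerated pairs. Expected pairs outside the enumerated universe
    are warned about, reported under 'expected_outside_universe', and ignored.
    """
    expected = set(expected)
    universe = set(zip(table["gene_id"], table["drug_id"]))
    outside = expected - universe
    if outside:
        warnings.warn(
            f"{len(outside)} expected pair(s) not in the enumerated universe; ignored",
            stacklevel=2,
        )
        expected = expected & universe
    table = table.copy()
    keys = list(zip(table["gene_id"], table["drug_id"]))
    table["expected"] = [k in expected for k in keys]
    sig = table["significant"].to_numpy(dtype=bool)
    exp = table["expected"].to_numpy(dtype=bool)
    venn = np.where(sig & exp, "TP", np.where(sig & ~exp, "FP",
                    np.where(~sig & exp, "FN", "TN")))
    table["venn_class"] = venn
    counts = {
        "TP": int((sig & exp).sum()),
        "FP": int((sig & ~exp).sum()),
        "FN": int((~sig & exp).sum()),
        "TN": int((~sig & ~exp).sum()),
        "total": int(len(table)),
        "expected_outside_universe": len(outside),
    }
    return table, counts


def rank_by_effect(table: pd.DataFrame, drug_means: Mapping[str, float] | pd.Series) -> pd.DataFrame:
    """rank_score = mean drug cytotoxicity x Fisher z (signed), sorted
    descending with (gene_id, drug_id) tie-break."""
    drug_means = pd.Series(drug_means)
    table = table.copy()
    table["mean_cytotoxicity"] = table["drug_id"].map(drug_means)
    table["rank_score"] = table["mean_cytotoxicity"] * table["z"]
    return table.sort_values(
        ["rank_score", "gene_id", "drug_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def verify_against_annotation_sets(
    table: pd.DataFrame, annotation_sets: Mapping[str, Iterable[tuple[str, str]]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag pairs present in >= 1 named annotation set.

    Returns (table with 'verified' column, per-set counts incl. union row).
    """
    sets = {name: set(pairs) for name, pairs in annotation_sets.items()}
    union: set[tuple[str, str]] = set().union(*sets.values()) if sets else set()
    keys = list(zip(table["gene_id"], table["drug_id"]))
    table = table.copy()
    table["verified"] = [k in union for k in keys]
    universe = set(keys)
    rows = [
        {"set": name, "n_pairs": len(s), "n_in_universe": len(s & universe)}
        for name, s in sets.items()
    ]
    rows.append({"set": "__union__", "n_pairs": len(union),
                 "n_in_universe": len(union & universe)})
    return table, pd.DataFrame(rows)
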