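"""Cross-study summary statistics over a table of per-study partition-test
results (81 published dinosaur matrices, shipped as a versioned CSV
fixture): significance tallies by clade, likelihood-ratio G tests of
heterogeneity, paired Wilcoxon signed-rank comparisons (reported as the
sum of positive-difference ranks, V), exact binomial/sign tests, Spearman
rank correlations, and the regression-residual comparison of consistency
indices that removes the dependence of CI on matrix dimensions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult", "CLADES", "load_table1_fixture", "tally_significance",
    "g_test", "wilcoxon_signed_rank_v", "exact_binomial_test",
    "spearman_rho", "ci_residual_compare", "association_consilience",
]

CLADES = ("Theropoda", "Sauropodomorpha", "Cerapoda", "Ornithopoda", "Thyreophora")
_CLADE_COUNTS = {"Theropoda": 29, "Sauropodomorpha": 17, "Cerapoda": 6,
                 "Ornithopoda": 15, "Thyreophora": 14}

TEST_COLUMNS = ("p_ild", "p_ird_nnd_rf", "p_ird_mr_rf",
                "p_ird_nnd_matching", "p_ird_mr_matching")

_FIXTURE_SHA256 = "f62bdebe703e55b5bb2787af31dc26128969ef33d2d0829b0b225f0b42efd052"


@dataclass
class StatResult:
    name: str
    value: float
    p_value: float
    df: float | None = None
    extra: dict | None = None

    def __repr__(self) -> str:
        df = f", df={self.df}" if self.df is not None else ""
        return f"StatResult({self.name}={self.value:.4f}{df}, p={self.p_value:.4g})"


def load_table1_fixture(path=None) -> pd.DataFrame:
    """The packaged per-study results table (one row per published matrix).

    Validates the checksum, the 81-row count, the per-clade tallies and the
    p-value ranges before returning.
    """
    if path is None:
        ref = resources.files("partcong").joinpath("data/table1.csv")
        raw = ref.read_bytes()
    else:
        with open(path, "rb") as fh:
            raw = fh.read()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError(
                f"fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}")
    if path is None:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError("packaged fixture is corrupted (checksum mismatch)")
    import io
    df = pd.read_csv(io.BytesIO(raw))
    if len(df) != 81:
        raise ValueError(f"expected 81 studies, found {len(df)}")
    counts = df["clade"].value_counts().to_dict()
    if counts != _CLADE_COUNTS:
        raise ValueError(f"unexpected clade tallies: {counts}")
    for col in TEST_COLUMNS:
        if not ((df[col] > 0) & (df[col] <= 1)).all():
            raise ValueError(f"{col} outside (0, 1]")
    return df


def tally_significance(table: pd.DataFrame, column: str, alpha: float = 0.05,
                       by: str | None = None):
    """Count studies with p < alpha, in total or per group."""
    if column not in table.columns:
        raise KeyError(column)
    sig = table[column] < alpha
    if by is None:
        return int(sig.sum())
    return sig.groupby(table[by]).sum().astype(int).to_dict()


def g_test(contingency) -> StatResult:
    """Likelihood-ratio G test on a k x m count table (0 ln 0 = 0)."""
    O = np.asarray(contingency, float)
    if np.any(O < 0):
        raise ValueError("negative counts")
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin in contingency table")
    E = rows * cols / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    G = float(2.0 * terms.sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return StatResult("G", G, float(stats.chi2.sf(G, df)), df=df)


def significance_table(table: pd.DataFrame, column: str, alpha: float = 0.05) -> np.ndarray:
    """5x2 (clade x significant/not) counts for a test column."""
    sig = np.array([
        ((table["clade"] == c) & (table[column] < alpha)).sum() for c in CLADES
    ], float)
    non = np.array([
        ((table["clade"] == c) & (table[column] >= alpha)).sum() for c in CLADES
    ], float)
    return np.column_stack([sig, non])


def wilcoxon_signed_rank_v(x, y) -> StatResult:
    """Paired signed-rank test; V = sum of average ranks of positive (x-y)
    differences after dropping zeros.  The p-value uses exact enumeration
    when there are no ties or zeros, otherwise the tie-corrected normal
    approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return StatResult("V", float("nan"), float("nan"),
                          extra={"degenerate": True})
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    p = float(stats.wilcoxon(x, y).pvalue)
    return StatResult("V", v, p, extra={"n_nonzero": int(d.size)})


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> StatResult:
    """Two-sided exact binomial test (sum of point probabilities no larger
    than that of the observed count)."""
    res = stats.binomtest(int(k), int(n), p0)
    return StatResult("binomial", k / n if n else float("nan"), float(res.pvalue))


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation (average ranks for ties), p via the
    t approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("rho", float("nan"), float("nan"),
                          extra={"degenerate": True})
    rho, p = stats.spearmanr(x, y)
    return StatResult("rho", float(rho), float(p))


def ci_residual_compare(table: pd.DataFrame, index: str = "ci") -> StatResult:
    """Compare partition homoplasy after removing matrix-dimension effects.

    Pools both partitions (2 observations per study), fits OLS of the index
    on log(#characters), log(#taxa) and their interaction, then runs the
    paired signed-rank test on craniodental vs postcranial residuals.
    """
    import statsmodels.api as sm

    cols = {"ci": ("ci_cranio", "ci_post"), "ri": ("ri_cranio", "ri_post")}
    c_col, p_col = cols[index]
    yy = np.concatenate([table[c_col], table[p_col]])
    chars = np.concatenate([table["n_cranio_chars"], table["n_post_chars"]]).astype(float)
    taxa = np.concatenate([table["n_taxa"], table["n_taxa"]]).astype(float)
    X = np.column_stack([np.log(chars), np.log(taxa), np.log(chars) * np.log(taxa)])
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(yy, X).fit()
    resid = fit.resid
    n = len(table)
    res = wilcoxon_signed_rank_v(resid[:n], resid[n:])
    res.extra = dict(res.extra or {}, model_p=float(fit.f_pvalue),
                     params=fit.params.tolist(), r2=float(fit.rsquared))
    return res


def association_consilience(table: pd.DataFrame, strat_winners) -> StatResult:
    """G test of association between the total-evidence winner (which
    partition's trees are closest to the entire matrix's) and the
    stratigraphic winner (which partition's trees fit the fossil record
    better), as a 2x2 table over studies."""
    winners = table.set_index("study")["winner"]
    cells = np.zeros((2, 2), float)
    for study, strat_side in strat_winners.items():
        i = 0 if winners.loc[study] == "Cranio" else 1
        j = 0 if strat_side == "Cranio" else 1
        cells[i, j] += 1
    return g_test(cells)
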