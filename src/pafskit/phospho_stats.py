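"""Filtering, normalization, batch correction and differential testing of
phosphosite intensity tables, plus subcellular fraction profiles.

The workflow mirrors standard multi-batch TMT phosphoproteomics practice:

1. keep confidently localized (class I) sites, localization probability
   >= 0.75;
2. variance-stabilize reporter intensities per TMT batch with an affine
   calibration followed by a generalized log2;
3. remove additive batch effects with a per-site linear model while
   preserving the condition contrast;
4. test treated vs control per site with an s0-moderated t statistic
   (SAM-style: t' = delta / (se + s0)) and Benjamini-Hochberg FDR.

Subcellular fractionation data reuse the same table container with a
fraction index per sample; scaled fraction profiles and coordinated
depletion/accumulation (translocation) calls are derived from per-fraction
differential results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhosphoSiteTable",
    "DifferentialConfig",
    "FilterReport",
    "TranslocationCall",
    "CalibrationError",
    "ConfoundingError",
    "filter_class1",
    "glog2",
    "vsn_transform",
    "batch_correct",
    "sam_test",
    "count_regulated",
    "scale_profiles",
    "call_translocation",
]

RESIDUES = frozenset("STY")


class CalibrationError(ValueError):
    """A sample has too few finite intensities to calibrate."""


class ConfoundingError(ValueError):
    """Batch is confounded with condition; correction would remove the effect."""


@dataclass
class PhosphoSiteTable:
    """Long-format phosphosite quantification.

    values : DataFrame, sites x samples (raw positive intensities, or log2
        when ``log2`` is True); NaN marks missing.
    sites : DataFrame indexed like ``values`` with columns ``protein``,
        ``position``, ``residue`` (S/T/Y), ``localization_prob`` and
        optionally ``window`` (+-6 aa sequence context, '_' padding).
    samples : DataFrame indexed by sample column with ``batch`` and
        ``condition`` labels, optional ``group`` and ``fraction``.
    """

    values: pd.DataFrame
    sites: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sites.index):
            raise ValueError("values and sites must share an index")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns and samples index must match")
        bad = set(self.sites["residue"]) - RESIDUES
        if bad:
            raise ValueError(f"residues must be S/T/Y, got {sorted(bad)}")
        probs = self.sites["localization_prob"]
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("localization_prob must be in [0, 1]")
        for col in ("batch", "condition"):
            if col not in self.samples.columns or self.samples[col].isna().any():
                raise ValueError(f"every sample needs a {col!r} label")
        if not self.log2 and (self.values <= 0).any().any():
            raise ValueError("raw intensities must be positive or missing (NaN)")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame, log2: bool | None = None) -> "PhosphoSiteTable":
        return PhosphoSiteTable(
            values=values,
            sites=self.sites.copy(),
            samples=self.samples.copy(),
            log2=self.log2 if log2 is None else log2,
        )


@dataclass(frozen=True)
class DifferentialConfig:
    """s0-moderated two-sided test configuration.

    s0 is the SAM fold-change stabilizer in log2 units added to the
    standard error (default 0.1); fdr is the BH target level (0.05).
    """

    s0: float = 0.1
    fdr: float = 0.05
    equal_var: bool = True  # pooled (Student) by default; False uses Welch

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


@dataclass(frozen=True)
class FilterReport:
    retained: int
    dropped: int
    by_residue: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TranslocationCall:
    protein: str
    depleted_fraction: int
    accumulated_fraction: int
    call: bool = True


def filter_class1(
    table: PhosphoSiteTable, threshold: float = 0.75
) -> tuple[PhosphoSiteTable, FilterReport]:
    """Keep class-I sites: localization probability >= threshold (inclusive)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    keep = table.sites["localization_prob"] >= threshold
    out = PhosphoSiteTable(
        values=table.values.loc[keep],
        sites=table.sites.loc[keep],
        samples=table.samples.copy(),
        log2=table.log2,
    )
    report = FilterReport(
        retained=int(keep.sum()),
        dropped=int((~keep).sum()),
        by_residue=out.sites["residue"].value_counts().to_dict(),
    )
    return out, report


def glog2(u, c: float):
    """Generalized log2: log2((u + sqrt(u^2 + c^2)) / 2).

    Reduces to log2(u) when c = 0 and approaches it for u >> c; stays
    finite for small or negative calibrated values.
    """
    u = np.asarray(u, dtype=float)
    return np.log2((u + np.sqrt(u**2 + c**2)) / 2.0)


def _sd_vs_mean_slope(h: np.ndarray) -> float:
    """Slope of per-site SD on per-site mean (rows with >= 2 finite)."""
    mean = np.nanmean(h, axis=1)
    sd = np.nanstd(h, axis=1, ddof=1)
    ok = np.isfinite(mean) & np.isfinite(sd)
    if ok.sum() < 3 or np.nanstd(mean[ok]) == 0:
        return 0.0
    return float(np.polyfit(mean[ok], sd[ok], 1)[0])


def vsn_transform(table: PhosphoSiteTable, min_finite: int = 10) -> PhosphoSiteTable:
    """Variance-stabilizing transform, fitted separately per batch.

    Two-step estimator: (1) per-sample affine calibration
    ``u = a_s + b_s * x`` with ``b_s = MAD_pool / MAD_s`` and
    ``a_s = med_pool - b_s * med_s`` (median/MAD are outlier-robust
    against regulated sites); (2) a single glog2 offset ``c`` per batch
    chosen on a quantile grid to flatten the per-site SD-vs-mean trend.
    The output is on a log2-like scale: for large intensities
    ``h(x) -> log2(x) + const``.
    """
    if table.log2:
        raise ValueError("vsn_transform expects raw (not log2) intensities")
    out = table.values.astype(float).copy()
    for batch in table.samples["batch"].unique():
        cols = table.samples.index[table.samples["batch"] == batch]
        x = table.values[cols].to_numpy(dtype=float)
        med = np.empty(len(cols))
        mad = np.empty(len(cols))
        for s in range(len(cols)):
            col = x[:, s]
            finite = col[np.isfinite(col)]
            if finite.size < min_finite:
                raise CalibrationError(
                    f"sample {cols[s]!r}: only {finite.size} finite values "
                    f"(need >= {min_finite}) for calibration"
                )
            med[s] = np.median(finite)
            mad[s] = stats.median_abs_deviation(finite)
            if mad[s] == 0:
                raise CalibrationError(f"sample {cols[s]!r}: zero MAD, cannot calibrate")
        med_pool, mad_pool = np.median(med), np.median(mad)
        b = mad_pool / mad
        a = med_pool - b * med
        u = a[None, :] + b[None, :] * x
        pos = u[np.isfinite(u) & (u > 0)]
        lo, hi = np.quantile(pos, [0.005, 0.5])
        candidates = np.geomspace(max(lo, 1e-12), hi, 25)
        slopes = [abs(_sd_vs_mean_slope(glog2(u, c))) for c in candidates]
        c_best = float(candidates[int(np.argmin(slopes))])
        out[cols] = glog2(u, c_best)
    return table.copy_with(out, log2=True)


def _design(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Covariate columns (intercept + condition) and sum-to-zero batch columns."""
    cond = pd.get_dummies(samples["condition"], drop_first=True).to_numpy(dtype=float)
    covar = np.column_stack([np.ones(len(samples)), cond]) if cond.size else np.ones(
        (len(samples), 1)
    )
    batches = pd.Categorical(samples["batch"])
    nb = len(batches.categories)
    codes = np.asarray(batches.codes)
    # contr.sum coding: nb - 1 columns, last batch = -1 on all
    bx = np.zeros((len(samples), nb - 1))
    for j in range(nb - 1):
        bx[codes == j, j] = 1.0
    bx[codes == nb - 1, :] = -1.0
    return covar, bx


def batch_correct(table: PhosphoSiteTable) -> PhosphoSiteTable:
    """Subtract additive per-site batch effects, preserving the condition term.

    Per site, fits ``y ~ covariates + batch`` (batch in sum-to-zero
    coding) by least squares and subtracts the fitted batch component —
    the same model as limma's removeBatchEffect.  A single batch is an
    identity map; batch perfectly confounded with condition raises
    rather than silently absorbing the effect.
    """
    if not table.log2:
        raise ValueError("batch_correct expects log-scale values")
    nb = table.samples["batch"].nunique()
    if nb < 2:
        return table.copy_with(table.values.copy())
    covar, bx = _design(table.samples)
    full = np.hstack([covar, bx])
    rank_covar = np.linalg.matrix_rank(covar)
    if np.linalg.matrix_rank(full) < rank_covar + bx.shape[1]:
        raise ConfoundingError(
            "batch is confounded with condition; batch effects are not estimable"
        )
    y = table.values.to_numpy(dtype=float)
    corrected = y.copy()
    complete = np.isfinite(y).all(axis=1)

    def correct_rows(rows: np.ndarray, mask: np.ndarray) -> None:
        beta, *_ = np.linalg.lstsq(full[mask], rows[:, mask].T, rcond=None)
        batch_part = bx[mask] @ beta[covar.shape[1] :]
        corrected[np.ix_(np.flatnonzero(sel), np.flatnonzero(mask))] = (
            rows[:, mask] - batch_part.T
        )

    sel = complete
    if sel.any():
        correct_rows(y[sel], np.ones(y.shape[1], dtype=bool))
    for i in np.flatnonzero(~complete):
        mask = np.isfinite(y[i])
        sub = np.hstack([covar[mask], bx[mask]])
        if np.linalg.matrix_rank(sub) < sub.shape[1]:
            continue  # not estimable for this site; leave as-is
        beta, *_ = np.linalg.lstsq(sub, y[i, mask], rcond=None)
        corrected[i, mask] = y[i, mask] - bx[mask] @ beta[covar.shape[1] :]
    return table.copy_with(
        pd.DataFrame(corrected, index=table.values.index, columns=table.values.columns)
    )


def _welch_components(x1: np.ndarray, x2: np.ndarray):
    """Vectorized per-row Welch pieces with NaN-aware counts."""
    n1 = np.isfinite(x1).sum(axis=1)
    n2 = np.isfinite(x2).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        v1 = np.nanvar(x1, axis=1, ddof=1)
        v2 = np.nanvar(x2, axis=1, ddof=1)
    return n1, n2, m1, m2, v1, v2


def _se_and_df(n1, n2, v1, v2, equal_var: bool):
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = (n1 + n2 - 2).astype(float)
        else:
            t1, t2 = v1 / n1, v2 / n2
            se = np.sqrt(t1 + t2)
            df = (t1 + t2) ** 2 / (t1**2 / (n1 - 1) + t2**2 / (n2 - 1))
    # zero within-group variance in both groups: se = 0 and Welch df is 0/0;
    # fall back to the pooled df so t' = delta / s0 still gets a p-value
    degen = ~np.isfinite(df)
    df[degen] = (n1 + n2 - 2)[degen]
    return se, df


def sam_test(
    table: PhosphoSiteTable,
    contrast: tuple[str, str] = ("treated", "control"),
    config: DifferentialConfig | None = None,
    permute_fdr: bool = False,
    n_permutations: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site two-sided t-test of ``contrast[0] - contrast[1]`` with an
    s0 (SAM-style) hyperbolic significance boundary.

    Per site: delta = mean difference (log2 fold change), se = pooled (or
    Welch) standard error, ordinary t = delta / se giving the two-sided
    p-value (pooled or Welch-Satterthwaite degrees of freedom) that is
    BH-adjusted across tested sites, and the moderated statistic
    t' = delta / (se + s0).  ``significant`` requires q < fdr *and*
    |t'| >= t_crit(df, fdr) — the analytic rendering of the hyperbolic
    volcano boundary: as se -> 0 it imposes the fold-change floor
    |delta| >= t_crit * s0 that s0 exists to provide.  At s0 = 0 the
    second condition is implied by the first (q >= p), so the test
    reduces exactly to the ordinary two-sample t-test.  Sites with fewer
    than two finite values in either group are reported with
    ``tested = False``; so are exactly-constant sites with delta = 0.

    ``permute_fdr`` replaces analytic p-values by sample-label permutation
    p-values (pooled null of |t'| over ``n_permutations`` shuffles of the
    condition labels, seeded) before BH — closer to SAM's
    permutation-calibrated cutoff; significance is then q < fdr alone.
    """
    config = config or DifferentialConfig()
    if not table.log2:
        raise ValueError("sam_test expects log2-scale values")
    g1 = table.samples.index[table.samples["condition"] == contrast[0]]
    g2 = table.samples.index[table.samples["condition"] == contrast[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"contrast {contrast} selects an empty group")
    x1 = table.values[g1].to_numpy(dtype=float)
    x2 = table.values[g2].to_numpy(dtype=float)

    n1, n2, m1, m2, v1, v2 = _welch_components(x1, x2)
    delta = m1 - m2
    se, df = _se_and_df(n1, n2, v1, v2, config.equal_var)
    tested = (n1 >= 2) & (n2 >= 2) & ~((se == 0) & (delta == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = delta / (se + config.s0)
        t_ord = delta / se
    p = np.full(delta.shape, np.nan)
    ok = tested & np.isfinite(t_mod)
    p[ok] = 2 * stats.t.sf(np.abs(t_ord[ok]), df[ok])
    # zero variance with nonzero delta: ordinary t is infinite, p -> 0
    p[ok & ~np.isfinite(t_ord)] = 0.0

    if permute_fdr:
        rng = np.random.default_rng(seed)
        x = np.hstack([x1, x2])
        labels = np.array([0] * x1.shape[1] + [1] * x2.shape[1])
        null_abs = []
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            p1, p2 = x[:, perm == 0], x[:, perm == 1]
            pn1, pn2, pm1, pm2, pv1, pv2 = _welch_components(p1, p2)
            pse, _ = _se_and_df(pn1, pn2, pv1, pv2, config.equal_var)
            with np.errstate(divide="ignore", invalid="ignore"):
                pt = (pm1 - pm2) / (pse + config.s0)
            null_abs.append(np.abs(pt[np.isfinite(pt)]))
        null = np.sort(np.concatenate(null_abs))
        # permutation p: fraction of pooled null |t'| >= observed (add-one)
        ranks = null.size - np.searchsorted(null, np.abs(t_mod[ok]), side="left")
        p[ok] = (ranks + 1) / (null.size + 1)

    q = np.full(delta.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    significant = np.where(np.isfinite(q), q < config.fdr, False) & tested
    if not permute_fdr and config.s0 > 0:
        # hyperbolic boundary: the moderated statistic must clear the
        # per-site critical t at the target FDR level
        t_crit = stats.t.isf(config.fdr / 2, df)
        significant &= np.abs(t_mod) >= t_crit
    direction = np.where(delta > 0, "up", np.where(delta < 0, "down", "none"))
    return pd.DataFrame(
        {
            "log2fc": delta,
            "t_mod": t_mod,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": direction,
            "tested": tested,
        },
        index=table.values.index,
    )


def count_regulated(result: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) among significant sites for the tested contrast."""
    sig = result[result["significant"]]
    return int((sig["direction"] == "up").sum()), int((sig["direction"] == "down").sum())


def scale_profiles(table: PhosphoSiteTable, by: str = "protein") -> pd.DataFrame:
    """Per-``by`` mean intensity per fraction, scaled to a max of 1.

    Rows are in [0, 1] with the maximum fraction exactly 1 — the scaled
    fraction profile used to visualize subcellular distributions.  Rows
    with no finite value in any fraction are dropped with a warning.
    """
    if "fraction" not in table.samples.columns or table.samples["fraction"].isna().any():
        raise ValueError("every sample needs a fraction index")
    fractions = sorted(table.samples["fraction"].unique())
    per_frac = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for f in fractions:
            cols = table.samples.index[table.samples["fraction"] == f]
            frac_mean = np.nanmean(table.values[cols].to_numpy(dtype=float), axis=1)
            per_frac[f] = (
                pd.Series(frac_mean, index=table.values.index)
                .groupby(table.sites[by])
                .mean()
            )
    prof = pd.DataFrame(per_frac)
    empty = prof.isna().all(axis=1)
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} {by}(s) with no finite intensities")
        prof = prof.loc[~empty]
    return prof.div(prof.max(axis=1), axis=0)


def call_translocation(
    dep: pd.DataFrame,
    acc: pd.DataFrame,
    depleted_fraction: int = 1,
    accumulated_fraction: int = 2,
) -> tuple[list[TranslocationCall], dict]:
    """Proteins significantly down in one fraction and up in another.

    ``dep`` and ``acc`` are differential results (indexed by protein)
    computed for the depleted and accumulated fraction under the same
    contrast.  Returns the calls plus the set sizes for the overlap
    diagram: n down in the depleted fraction, n up in the accumulated
    fraction, and the intersection.
    """
    common = dep.index.intersection(acc.index)
    if common.empty:
        warnings.warn("translocation: protein sets are disjoint between fractions")
        return [], {"n_down_depleted": 0, "n_up_accumulated": 0, "n_called": 0}
    down = set(dep.index[(dep["significant"]) & (dep["direction"] == "down")])
    up = set(acc.index[(acc["significant"]) & (acc["direction"] == "up")])
    called = sorted(down & up)
    calls = [
        TranslocationCall(
            protein=p,
            depleted_fraction=depleted_fraction,
            accumulated_fraction=accumulated_fraction,
        )
        for p in called
    ]
    summary = {
        "n_down_depleted": len(down),
        "n_up_accumulated": len(up),
        "n_called": len(called),
    }
    return calls, summary
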