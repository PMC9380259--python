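"""Functional-score ranking (PAFS), kinase-substrate enrichment (KSEA),
sequence-motif overrepresentation, gene-set ORA and set-overlap statistics.

PAFS joins significantly regulated phosphosites to a per-site functional
score in [0, 1] (machine-learned relevance, consumed as a table) and
selects sites scoring strictly above a threshold (default 0.6).

KSEA infers a kinase activity z-score from the log2 fold changes of its
annotated substrates against the all-measured-site background:

    z = (mean_substrates - mean_background) * sqrt(m) / sd_background

with a two-sided normal p-value; kinases with fewer than
``min_substrates`` measured substrates are omitted.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pafs_rank",
    "ksea",
    "motif_enrichment",
    "set_ora",
    "overlap_coefficient",
    "strip_isoform",
]

PAD = "_"
WINDOW_LEN = 13  # +-6 residues around the phosphosite


def strip_isoform(protein: str) -> str:
    """Drop an isoform suffix from a protein accession (P04637-2 -> P04637)."""
    return re.sub(r"-\d+$", "", protein)


def pafs_rank(
    diff: pd.DataFrame,
    sites: pd.DataFrame,
    scores: pd.DataFrame,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Rank significant sites by functional score; select score > threshold.

    ``diff`` is a differential result indexed by site id; ``sites`` maps
    the same index to (protein, position); ``scores`` has columns
    protein, position, score.  Isoform suffixes are stripped from protein
    accessions before joining.  Output is sorted by descending score with
    ``selected`` marking significant sites strictly above the threshold;
    unscored significant sites are excluded and counted via a warning and
    the ``n_unscored`` attribute.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    sig = diff[diff["significant"]]
    if scores.empty:
        warnings.warn("empty functional-score table: PAFS ranking is empty")
        out = pd.DataFrame(
            columns=["protein", "position", "log2fc", "direction", "functional_score", "selected"]
        )
        out.attrs["n_unscored"] = int(len(sig))
        return out
    key = scores.assign(protein=scores["protein"].map(strip_isoform))
    key = key.drop_duplicates(subset=["protein", "position"])
    joined = (
        sig.drop(columns=["protein", "position"], errors="ignore")
        .join(sites[["protein", "position"]])
        .assign(protein=lambda d: d["protein"].map(strip_isoform))
        .merge(key[["protein", "position", "score"]], on=["protein", "position"], how="left")
        .set_index(sig.index)
    )
    n_unscored = int(joined["score"].isna().sum())
    if n_unscored:
        warnings.warn(f"PAFS: {n_unscored} significant site(s) without a functional score")
    ranked = joined.dropna(subset=["score"]).rename(columns={"score": "functional_score"})
    ranked["selected"] = ranked["functional_score"] > threshold
    cols = ["protein", "position", "log2fc", "direction", "functional_score", "selected"]
    if "group" in ranked.columns:
        cols.insert(4, "group")
    ranked = ranked[cols].sort_values(
        ["functional_score", "protein", "position"], ascending=[False, True, True]
    )
    ranked.attrs["n_unscored"] = n_unscored
    return ranked


def ksea(
    diff: pd.DataFrame,
    sites: pd.DataFrame,
    kinase_map: pd.DataFrame,
    min_substrates: int = 3,
) -> pd.DataFrame:
    """Kinase activity z-scores from substrate log2 fold changes.

    Background is *all measured sites* (every tested site's log2fc), not
    only the significant ones.  ``kinase_map`` has columns kinase,
    protein, position.  Returns one row per kinase with m >= min_substrates
    measured substrates: columns m, z, p; ``attrs['n_omitted']`` counts
    kinases dropped for having too few measured substrates.
    """
    if min_substrates < 1:
        raise ValueError("min_substrates must be >= 1")
    measured = diff[diff["tested"]] if "tested" in diff.columns else diff
    fc = measured["log2fc"].to_numpy(dtype=float)
    if fc.size == 0 or kinase_map.empty:
        out = pd.DataFrame(columns=["kinase", "m", "z", "p"])
        out.attrs["n_omitted"] = int(kinase_map["kinase"].nunique()) if not kinase_map.empty else 0
        return out
    bg_mean = float(np.mean(fc))
    bg_sd = float(np.std(fc, ddof=1))
    if bg_sd == 0:
        raise ValueError("degenerate background: all log2 fold changes are identical")
    site_fc = pd.Series(
        fc,
        index=pd.MultiIndex.from_frame(
            sites.loc[measured.index, ["protein", "position"]]
        ),
    )
    site_fc = site_fc[~site_fc.index.duplicated()]
    rows, omitted = [], 0
    for kin, sub in kinase_map.groupby("kinase"):
        keys = pd.MultiIndex.from_frame(sub[["protein", "position"]]).drop_duplicates()
        hit = site_fc.index.intersection(keys)
        m = len(hit)
        if m < min_substrates:
            omitted += 1
            continue
        s_mean = float(site_fc.loc[hit].mean())
        z = (s_mean - bg_mean) * np.sqrt(m) / bg_sd
        rows.append({"kinase": kin, "m": m, "z": z, "p": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows, columns=["kinase", "m", "z", "p"])
    if not out.empty:
        out = out.sort_values("z", ascending=False).reset_index(drop=True)
    out.attrs["n_omitted"] = omitted
    return out


def motif_enrichment(
    fg_windows: list[str],
    bg_windows: list[str],
    alpha: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-(position, residue) hypergeometric enrichment of +-6 aa windows.

    Windows are 13-mers with the phosphosite at index 6 and ``_`` padding
    at sequence ends; padded cells contribute no counts.  For each flank
    position (-6..+6 except 0) and residue, the upper-tail hypergeometric
    p-value of the foreground count given the background composition is
    computed; ``enriched`` means p < alpha (fixed-alpha by default, BH
    across all cells when ``adjust``).
    """
    if not fg_windows:
        raise ValueError("foreground window set is empty")
    if len(bg_windows) < len(fg_windows):
        raise ValueError("background must be at least as large as the foreground")
    for w in list(fg_windows) + list(bg_windows):
        if len(w) != WINDOW_LEN:
            raise ValueError(f"windows must be length {WINDOW_LEN}, got {w!r}")
    rows = []
    for idx in range(WINDOW_LEN):
        offset = idx - WINDOW_LEN // 2
        if offset == 0:
            continue
        fg_col = [w[idx] for w in fg_windows if w[idx] != PAD]
        bg_col = [w[idx] for w in bg_windows if w[idx] != PAD]
        M, N = len(bg_col), len(fg_col)
        bg_counts = pd.Series(bg_col).value_counts()
        fg_counts = pd.Series(fg_col).value_counts()
        for residue, k in fg_counts.items():
            n = int(bg_counts.get(residue, 0))
            p = float(stats.hypergeom.sf(int(k) - 1, M, n, N))
            rows.append(
                {
                    "position": offset,
                    "residue": residue,
                    "fg_count": int(k),
                    "bg_count": n,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows, columns=["position", "residue", "fg_count", "bg_count", "p"])
    if adjust and not out.empty:
        out["p"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = out["p"] < alpha
    return out.sort_values(["position", "p"]).reset_index(drop=True)


def set_ora(
    selected: set,
    universe: set,
    gene_sets: dict[str, set],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each gene set, BH-adjusted.

    Per set: p = P(overlap >= observed) for |selected| draws from a
    universe containing |universe & set| set members.
    """
    selected, universe = set(selected), set(universe)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected identifiers outside the universe: {sorted(stray)}")
    M, N = len(universe), len(selected)
    rows = []
    for name, members in gene_sets.items():
        in_universe = universe & set(members)
        k = len(selected & in_universe)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_universe), N))
        rows.append({"set": name, "overlap": k, "set_size": len(in_universe), "p": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if not out.empty else []
    return out.sort_values("p").reset_index(drop=True)


def overlap_coefficient(a: set, b: set) -> float:
    """Szymkiewicz-Simpson index: |a & b| / min(|a|, |b|)."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("overlap coefficient is undefined for two empty sets")
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))
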