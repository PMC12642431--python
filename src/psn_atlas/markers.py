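"""Subtype markers, expression repertoires, and ligand-receptor pairing.

Marker derivation follows the all-pairs-intersection logic: every subtype is
compared against every other subtype individually (two-sided Wilcoxon
rank-sum on log2(TPM+1) with Benjamini-Hochberg correction within each
pairwise comparison), and a gene counts as enriched in a subtype only if it
is significantly up against *every* other subtype. By construction no gene
can be enriched in two subtypes. The rank-sum test is a deliberate,
documented stand-in for heavier single-cell error models; the intersection
logic is the defining computation and is preserved exactly.

"Detectable" expression means TPM >= 1 everywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError

__all__ = [
    "pairwise_de",
    "intersect_markers",
    "dotplot_stats",
    "prevalence_screen",
    "annotate_subtypes",
    "scale_abundance",
    "pair_ligand_receptor",
    "LRPair",
]

TPM_DETECT = 1.0  # detectability threshold


@dataclass
class LRPair:
    ligand: str
    receptor: str
    source: list[str]
    target: list[str]
    direction: str  # "psn→immune" or "immune→psn"


def _groups(matrix: ad.AnnData, labels: pd.Series) -> dict[str, np.ndarray]:
    labels = labels.reindex(matrix.obs_names)
    X = np.asarray(matrix.X, dtype=float)
    out = {}
    for name in labels.dropna().unique():
        out[str(name)] = X[(labels == name).to_numpy()]
    return out


def pairwise_de(matrix: ad.AnnData, labels: pd.Series) -> pd.DataFrame:
    """All-pairs differential expression.

    For every ordered subtype pair (a, b) and every gene: two-sided
    Mann-Whitney/Wilcoxon rank-sum on log2(TPM+1), tie-corrected normal
    approximation, BH-adjusted within the pair. Effect is the log2 fold
    change of mean (TPM+1). Subtypes with < 2 cells are skipped (recorded in
    the frame's ``attrs["skipped"]``).

    Returns a tidy frame with columns gene, subtype_a, subtype_b, effect,
    p_value, q_value.
    """
    groups = _groups(matrix, labels)
    skipped = [k for k, v in groups.items() if len(v) < 2]
    names = sorted(k for k in groups if k not in skipped)
    genes = np.asarray(matrix.var_names)
    frames = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.log2(groups[a] + 1.0)
            xb = np.log2(groups[b] + 1.0)
            res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided", method="asymptotic")
            p = np.asarray(res.pvalue)
            # constant genes carry no ranking information
            const = (np.ptp(xa, axis=0) == 0) & (np.ptp(xb, axis=0) == 0) & (
                xa[0] == xb[0]
            )
            p = np.where(const, 1.0, p)
            q = multipletests(p, method="fdr_bh")[1]
            eff = np.log2(groups[a].mean(axis=0) + 1.0) - np.log2(groups[b].mean(axis=0) + 1.0)
            na, nb = len(xa), len(xb)
            # smallest two-sided p the rank-sum test can attain at these n
            p_floor = 2.0 / comb(na + nb, min(na, nb), exact=True)
            for s_a, s_b, e in ((a, b, eff), (b, a, -eff)):
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": genes,
                            "subtype_a": s_a,
                            "subtype_b": s_b,
                            "effect": e,
                            "p_value": p,
                            "q_value": q,
                            "n_a": na if s_a == a else nb,
                            "n_b": nb if s_a == a else na,
                            "p_floor": p_floor,
                        }
                    )
                )
    if not frames:
        raise InputError("no subtype with >= 2 cells")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["skipped"] = skipped
    return out


def intersect_markers(
    results: pd.DataFrame, alpha: float = 0.01, min_effect: float = 1.0
) -> pd.DataFrame:
    """Intersect the pairwise DE lists into per-subtype enriched genes.

    A gene is enriched in subtype ``s`` iff q < ``alpha`` and effect >
    ``min_effect`` against *every* other subtype individually.

    Comparisons against very small groups (e.g. a two-cell rare cluster)
    cannot certify significance under the rank-sum test once BH-corrected,
    and would otherwise veto every gene genome-wide. A pairwise comparison
    is therefore considered *powered* only if it certified at least one
    gene (min q <= alpha); unpowered comparisons fall back to the effect
    criterion alone, and a subtype none of whose comparisons is powered
    receives no markers at all rather than effect-only ones.

    Returns one row per enriched gene with the weakest evidence over all
    comparisons (min effect, max q) and a per-subtype specificity rank by
    min effect.
    """
    subtypes = sorted(set(results["subtype_a"]).union(results["subtype_b"]))
    expected = {(a, b) for a in subtypes for b in subtypes if a != b}
    present = set(zip(results["subtype_a"], results["subtype_b"]))
    missing = sorted(expected - present)
    if missing:
        raise InputError(f"missing pairwise comparisons: {missing}")
    pair_min_q = results.groupby(["subtype_a", "subtype_b"])["q_value"].min()
    powered_pair = pair_min_q <= alpha
    rows = []
    for s, df in results.groupby("subtype_a"):
        n_required = len(subtypes) - 1
        if not powered_pair.loc[s].any():
            continue  # no comparison can certify anything for this subtype
        powered = df.set_index("subtype_b").index.map(powered_pair.loc[s]).to_numpy()
        sig = df[((df["q_value"] < alpha) | ~powered) & (df["effect"] > min_effect)]
        counts = sig.groupby("gene").size()
        enriched = counts[counts == n_required].index
        if len(enriched) == 0:
            continue
        stats_df = (
            df[df["gene"].isin(enriched)]
            .groupby("gene")
            .agg(min_effect=("effect", "min"), max_q=("q_value", "max"))
            .reset_index()
        )
        stats_df["subtype"] = s
        rows.append(stats_df)
    if not rows:
        return pd.DataFrame(columns=["gene", "subtype", "min_effect", "max_q", "rank"])
    table = pd.concat(rows, ignore_index=True)
    table["rank"] = table.groupby("subtype")["min_effect"].rank(ascending=False, method="first")
    assert not table["gene"].duplicated().any(), "marker exclusivity violated"
    return table[["gene", "subtype", "min_effect", "max_q", "rank"]]


def dotplot_stats(matrix: ad.AnnData, labels: pd.Series, genes: list[str]) -> pd.DataFrame:
    """Fraction of expressing cells (TPM >= 1) and mean log2(TPM+1) per
    gene x subtype. Unknown genes are listed in ``attrs["missing"]``; the
    mean is taken over all cells of the subtype, expressing or not."""
    present = [g for g in genes if g in matrix.var_names]
    missing = [g for g in genes if g not in matrix.var_names]
    groups = _groups(matrix[:, present], labels) if present else {}
    col = {g: i for i, g in enumerate(present)}
    rows = []
    for subtype, X in sorted(groups.items()):
        logx = np.log2(X + 1.0)
        for g in present:
            j = col[g]
            rows.append(
                {
                    "gene": g,
                    "subtype": subtype,
                    "frac_expressing": float((X[:, j] >= TPM_DETECT).mean()),
                    "mean_log_expr": float(logx[:, j].mean()),
                }
            )
    out = pd.DataFrame(rows, columns=["gene", "subtype", "frac_expressing", "mean_log_expr"])
    out.attrs["missing"] = missing
    return out


def prevalence_screen(
    matrix: ad.AnnData, labels: pd.Series, panel: list[str], min_frac: float = 0.5
) -> list[str]:
    """Genes detectably expressed in more than ``min_frac`` of cells of at
    least one subtype (strict inequality)."""
    if not panel:
        return []
    st = dotplot_stats(matrix, labels, panel)
    if st.empty:
        return []
    hits = st[st["frac_expressing"] > min_frac]["gene"].unique()
    return [g for g in panel if g in set(hits)]


def annotate_subtypes(
    matrix: ad.AnnData,
    labels: pd.Series,
    nefh_gene: str = "Nefh",
    phox2b_gene: str = "Phox2b",
    fiber_cutpoints: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-subtype fiber-type and developmental-lineage annotation.

    Lineage is ``crest`` iff the subtype's median Phox2b TPM is below the
    detectability threshold, else ``placode``. Fiber class comes from the
    subtype's median Nefh log2(TPM+1) against two cut points (defaults:
    terciles of the subtype medians): C-like below the first cut,
    Aδ-like between, Aβ-like above.
    """
    for g in (nefh_gene, phox2b_gene):
        if g not in matrix.var_names:
            raise InputError(f"gene {g!r} absent from matrix")
    X = np.asarray(matrix[:, [nefh_gene, phox2b_gene]].X, dtype=float)
    lab = labels.reindex(matrix.obs_names)
    rows = {}
    for s in sorted(lab.dropna().unique()):
        m = (lab == s).to_numpy()
        rows[str(s)] = {
            "nefh_median_log": float(np.median(np.log2(X[m, 0] + 1.0))),
            "phox2b_median_tpm": float(np.median(X[m, 1])),
        }
    df = pd.DataFrame(rows).T
    if fiber_cutpoints is None:
        fiber_cutpoints = tuple(np.quantile(df["nefh_median_log"], [1 / 3, 2 / 3]))
    c1, c2 = fiber_cutpoints
    df["fiber"] = np.where(
        df["nefh_median_log"] < c1, "C-like", np.where(df["nefh_median_log"] < c2, "Aδ-like", "Aβ-like")
    )
    df["lineage"] = np.where(df["phox2b_median_tpm"] < TPM_DETECT, "crest", "placode")
    df.index.name = "subtype"
    return df


def scale_abundance(counts: dict[str, float] | pd.Series, total: float = 400.0) -> pd.DataFrame:
    """Scale observed subtype counts to an estimated census per ganglion.

    ``counts`` may be raw cell counts or independently estimated
    proportions (which need not sum to 1). The raw values are kept
    alongside the renormalized proportions, and scaled counts use the
    renormalized proportions so they sum to ``total``. The raw total is
    stored in ``attrs["raw_total"]``.
    """
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise InputError("counts must be non-negative")
    tot = float(s.sum())
    if tot <= 0:
        raise InputError("all counts are zero")
    out = pd.DataFrame(
        {"raw": s, "proportion": s / tot, "scaled_count": s / tot * total}
    )
    out.index.name = "subtype"
    out.attrs["raw_total"] = tot
    return out


def pair_ligand_receptor(
    psn_stats: pd.DataFrame,
    immune_table: pd.DataFrame,
    pairing_table: pd.DataFrame,
    min_frac: float = 0.5,
) -> tuple[list[LRPair], list[str]]:
    """Pair sensory-neuron ligands/receptors with immune-cell counterparts.

    ``psn_stats`` is a dot-plot table (gene, subtype, frac_expressing) for
    the neurons; ``immune_table`` gives (gene, cell_type, frac_expressing)
    for lung immune populations; ``pairing_table`` maps ligand -> receptor
    gene symbols. For each mapping row two directions are evaluated:

    - neuron→immune: the ligand passes the prevalence rule (> ``min_frac``
      of cells in >= 1 subtype) on the neuron side and the receptor is
      expressed at >= ``min_frac`` in >= 1 immune type;
    - immune→neuron: roles reversed (ligand on immune side, receptor on the
      neuron side under the prevalence rule).

    Returns (pairs, warnings); a mapping entry whose genes are absent from
    both tables is reported as a warning, not an error.
    """
    warnings: list[str] = []
    pairs: list[LRPair] = []

    def psn_hits(gene: str) -> list[str]:
        df = psn_stats[(psn_stats["gene"] == gene) & (psn_stats["frac_expressing"] > min_frac)]
        return sorted(df["subtype"].unique())

    def immune_hits(gene: str) -> list[str]:
        df = immune_table[
            (immune_table["gene"] == gene) & (immune_table["frac_expressing"] >= min_frac)
        ]
        return sorted(df["cell_type"].unique())

    known = set(psn_stats["gene"]).union(immune_table["gene"])
    for _, row in pairing_table.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        if lig not in known and rec not in known:
            warnings.append(f"pair {lig}->{rec}: neither gene found")
            continue
        src, tgt = psn_hits(lig), immune_hits(rec)
        if src and tgt:
            pairs.append(LRPair(lig, rec, src, tgt, "psn→immune"))
        src_i, tgt_p = immune_hits(lig), psn_hits(rec)
        if src_i and tgt_p:
            pairs.append(LRPair(lig, rec, src_i, tgt_p, "immune→psn"))
    return pairs, warnings
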