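"""Integration of GWAS and TWAS evidence into candidate genes.

Per trait: the top 10% of GWAS SNPs are assigned to their nearest gene, each
gene keeps its most significant assigned SNP, the gene's GWAS p is paired
with its TWAS p (1 when the gene is unexpressed), and the pair is combined
with Fisher's method (chi-square with 4 df).  Candidate genes are declared by
top-fraction rules per method, partitioned into confidence groups by the
agreement of the three methods, and intersected across phenotype families
(wax traits vs g_c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import top_k
from .synthdata import GenomeLayout


@dataclass
class Locus:
    """A declared GWAS locus: peak SNP plus absorbed top SNPs."""

    trait_id: str
    chrom: str
    pos: int
    p: float
    peak_snp: str
    members: list[str] = field(default_factory=list)
    wax_class: str | None = None


@dataclass
class ConfidenceGroups:
    group1: dict[str, dict]
    group2: dict[str, dict]
    group3: dict[str, dict]

    def all_genes(self) -> set[str]:
        return set(self.group1) | set(self.group2) | set(self.group3)


# ---------------------------------------------------------------------------
# Nearest gene
# ---------------------------------------------------------------------------


def nearest_gene_assignment(snp_table: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Assign each SNP to the gene nearest to its position.

    Distance is measured to the gene interval (0 when the SNP lies inside);
    ties break toward the smaller gene start, then the lexicographically
    smaller gene id.  SNPs on chromosomes without genes are left unassigned
    (logged with a warning).

    ``snp_table`` needs columns snp_id, chrom, pos (and is passed through).
    """
    out_rows = []
    genes = layout.genes
    unassigned = 0
    for chrom, sub in snp_table.groupby("chrom", sort=False):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            unassigned += len(sub)
            continue
        g = g.sort_values(["start", "gene_id"], kind="mergesort")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ids = g["gene_id"].to_numpy()
        pos = sub["pos"].to_numpy()
        # candidate genes: the interval-wise predecessor and successor
        nxt = np.searchsorted(starts, pos, side="right")  # first gene with start > pos
        prev = nxt - 1
        dist = np.full((len(pos), 2), np.inf)
        ok_prev = prev >= 0
        dist[ok_prev, 0] = np.maximum(pos[ok_prev] - ends[prev[ok_prev]], 0)
        ok_nxt = nxt < len(starts)
        dist[ok_nxt, 1] = starts[nxt[ok_nxt]] - pos[ok_nxt]
        # ties at equal distance go to the earlier-start (prev) gene
        choose_prev = dist[:, 0] <= dist[:, 1]
        gi = np.where(choose_prev, prev, np.minimum(nxt, len(starts) - 1))
        d = np.where(choose_prev, dist[:, 0], dist[:, 1])
        for row, g_idx, dd in zip(sub.itertuples(index=False), gi, d):
            out_rows.append((*row, ids[g_idx], int(dd)))
    if unassigned:
        warnings.warn(f"{unassigned} SNPs on chromosomes without genes were left unassigned")
    cols = list(snp_table.columns) + ["gene_id", "distance"]
    return pd.DataFrame(out_rows, columns=cols)


# ---------------------------------------------------------------------------
# Fisher's combined test
# ---------------------------------------------------------------------------


def fisher_combine(p_gwas, p_twas):
    """Fisher's method for one (GWAS, TWAS) pair: chi2_4 survival at -2 sum ln p.

    For two p-values the survival function has the closed form
    exp(-X/2) (1 + X/2) with X = -2 (ln p1 + ln p2).  Zero inputs are floored
    at the smallest positive normal float with a warning.
    """
    p1 = np.asarray(p_gwas, float)
    p2 = np.asarray(p_twas, float)
    if (p1 > 1).any() or (p2 > 1).any() or (p1 < 0).any() or (p2 < 0).any():
        raise ValueError("p-values must lie in (0, 1]")
    tiny = np.finfo(float).tiny
    if (p1 == 0).any() or (p2 == 0).any():
        warnings.warn("p = 0 input floored at the smallest positive normal float")
        p1 = np.maximum(p1, tiny)
        p2 = np.maximum(p2, tiny)
    X = -2.0 * (np.log(p1) + np.log(p2))
    out = stats.chi2.sf(X, df=4)
    return float(out) if np.isscalar(p_gwas) and np.isscalar(p_twas) else out


def fct_scan(
    gwas_table: pd.DataFrame,
    twas_table: pd.DataFrame,
    layout: GenomeLayout,
    snp_top_frac: float = 0.10,
) -> pd.DataFrame:
    """Fisher's combined test over paired GWAS/TWAS evidence for one trait.

    The top ``snp_top_frac`` of SNPs by GWAS p enter nearest-gene assignment;
    per gene only the most significant SNP-gene pair is kept; genes absent
    from TWAS ("unexpressed") contribute p = 1 on the TWAS side, which lets
    GWAS-only genes enter the test.  Genes with neither an assigned SNP nor
    expression are absent from the output.
    """
    if gwas_table.empty:
        raise ValueError("empty GWAS table")
    k = top_k(snp_top_frac, len(gwas_table))
    top = gwas_table.nsmallest(k, "p", keep="first")
    assigned = nearest_gene_assignment(
        top.rename(columns={"feature_id": "snp_id"})[["snp_id", "chrom", "pos", "p"]], layout
    )
    twas_p = dict(zip(twas_table["feature_id"], twas_table["p"]))
    rows = []
    if not assigned.empty:
        best = assigned.sort_values("p", kind="mergesort").drop_duplicates("gene_id")
        for r in best.itertuples(index=False):
            rows.append((r.gene_id, r.p, twas_p.get(r.gene_id, 1.0), r.snp_id))
    covered = {r[0] for r in rows}
    for g, p2 in twas_p.items():
        if g not in covered:
            rows.append((g, 1.0, p2, None))
    df = pd.DataFrame(rows, columns=["feature_id", "p_gwas", "p_twas", "peak_snp"])
    df["p"] = fisher_combine(df["p_gwas"].to_numpy(), df["p_twas"].to_numpy())
    df["trait_id"] = gwas_table["trait_id"].iloc[0] if "trait_id" in gwas_table else "trait"
    df["method"] = "FCT"
    df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Candidate declaration
# ---------------------------------------------------------------------------


def declare_gwas_loci(
    gwas_table: pd.DataFrame,
    top_frac: float = 2e-5,
    clump_bp: int = 200_000,
    trait_id: str | None = None,
    wax_class: str | None = None,
) -> list[Locus]:
    """Declare trait-associated loci from the top fraction of GWAS SNPs.

    The k = max(1, round(top_frac * N)) smallest-p SNPs are greedily clumped:
    the most significant unclustered SNP becomes a peak and absorbs top SNPs
    within ``clump_bp`` on the same chromosome.
    """
    if gwas_table.empty:
        raise ValueError("GWAS table has no SNPs")
    k = top_k(top_frac, len(gwas_table))
    top = gwas_table.nsmallest(k, "p", keep="first").sort_values("p", kind="mergesort")
    trait = trait_id or (gwas_table["trait_id"].iloc[0] if "trait_id" in gwas_table else "trait")
    loci: list[Locus] = []
    remaining = top.copy()
    while not remaining.empty:
        peak = remaining.iloc[0]
        near = remaining[
            (remaining["chrom"] == peak["chrom"])
            & (np.abs(remaining["pos"] - peak["pos"]) <= clump_bp)
        ]
        loci.append(
            Locus(
                trait_id=trait,
                chrom=str(peak["chrom"]),
                pos=int(peak["pos"]),
                p=float(peak["p"]),
                peak_snp=str(peak["feature_id"]),
                members=list(near["feature_id"]),
                wax_class=wax_class,
            )
        )
        remaining = remaining.drop(near.index)
    return loci


def select_candidates(
    loci: list[Locus],
    layout: GenomeLayout,
    twas_table: pd.DataFrame | None = None,
    fct_table: pd.DataFrame | None = None,
    interval_bp: int = 200_000,
    gene_top_frac: float = 2.5e-3,
) -> dict[str, pd.DataFrame]:
    """Candidate genes per method.

    GWAS candidates are genes whose interval overlaps the +/- ``interval_bp``
    window around a declared locus peak; TWAS and FCT candidates are the top
    ``gene_top_frac`` of genes tested by that method.  Each set carries ranks
    (and the peak SNP for GWAS entries).
    """
    out: dict[str, pd.DataFrame] = {}
    rows = []
    genes = layout.genes
    for loc in loci:
        lo, hi = loc.pos - interval_bp, loc.pos + interval_bp
        g = genes[(genes["chrom"] == loc.chrom) & (genes["end"] >= lo) & (genes["start"] <= hi)]
        for r in g.itertuples(index=False):
            rows.append((r.gene_id, loc.trait_id, loc.peak_snp, loc.p))
    gw = pd.DataFrame(rows, columns=["gene_id", "trait_id", "peak_snp", "peak_p"])
    gw = gw.sort_values("peak_p", kind="mergesort").drop_duplicates("gene_id").reset_index(drop=True)
    gw["rank"] = np.arange(1, len(gw) + 1)
    out["GWAS"] = gw
    for name, tab in (("TWAS", twas_table), ("FCT", fct_table)):
        if tab is None:
            continue
        k = top_k(gene_top_frac, len(tab))
        sel = tab.nsmallest(k, "p", keep="first").sort_values("p", kind="mergesort").reset_index(drop=True)
        sel = sel.rename(columns={"feature_id": "gene_id"})
        cols = ["gene_id", "p"] + (["trait_id"] if "trait_id" in sel else [])
        sel = sel[cols]
        sel["rank"] = np.arange(1, len(sel) + 1)
        out[name] = sel
    return out


# ---------------------------------------------------------------------------
# Confidence groups and shared candidates
# ---------------------------------------------------------------------------


def confidence_groups(
    candidates_by_trait: dict[str, dict[str, pd.DataFrame]],
    class_map: dict[str, str],
) -> ConfidenceGroups:
    """Partition genes detected by all three methods into confidence groups.

    Group 1: some single trait is hit by GWAS, TWAS and FCT for the gene.
    Group 2: not group 1, but the three methods all hit traits of one shared
    wax class.  Group 3: the rest of the genes detected by all three methods.
    """
    hits: dict[str, dict[str, set[str]]] = {}
    for trait, per_method in candidates_by_trait.items():
        for method, df in per_method.items():
            if df is None or df.empty:
                continue
            for g in df["gene_id"]:
                hits.setdefault(g, {m: set() for m in ("GWAS", "TWAS", "FCT")})[method].add(trait)
    g1, g2, g3 = {}, {}, {}
    for gene, by_method in hits.items():
        if not all(by_method[m] for m in ("GWAS", "TWAS", "FCT")):
            continue
        evidence = {m: sorted(ts) for m, ts in by_method.items()}
        common_traits = by_method["GWAS"] & by_method["TWAS"] & by_method["FCT"]
        if common_traits:
            g1[gene] = {"traits": sorted(common_traits), "evidence": evidence}
            continue
        class_sets = [{class_map.get(t) for t in by_method[m]} - {None} for m in ("GWAS", "TWAS", "FCT")]
        shared = set.intersection(*class_sets) if all(class_sets) else set()
        if shared:
            g2[gene] = {"classes": sorted(shared), "evidence": evidence}
        else:
            g3[gene] = {"evidence": evidence}
    return ConfidenceGroups(group1=g1, group2=g2, group3=g3)


def shared_candidates(
    gc_candidates: dict[str, pd.DataFrame],
    wax_candidates_by_trait: dict[str, dict[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Genes detected for g_c and for at least one wax trait, per method.

    Returns a table (gene_id, method, wax_traits, multi_method) where
    ``multi_method`` flags genes appearing in the intersection for more than
    one method.
    """
    wax_hits: dict[str, dict[str, set[str]]] = {}
    for trait, per_method in wax_candidates_by_trait.items():
        for method, df in per_method.items():
            if df is None or df.empty:
                continue
            for g in df["gene_id"]:
                wax_hits.setdefault(method, {}).setdefault(g, set()).add(trait)
    rows = []
    for method, df in gc_candidates.items():
        if df is None or df.empty:
            continue
        per_gene = wax_hits.get(method, {})
        for g in df["gene_id"].unique():
            if g in per_gene:
                rows.append((g, method, sorted(per_gene[g])))
    out = pd.DataFrame(rows, columns=["gene_id", "method", "wax_traits"])
    if out.empty:
        out["multi_method"] = pd.Series(dtype=bool)
        return out
    counts = out.groupby("gene_id")["method"].nunique()
    out["multi_method"] = out["gene_id"].map(counts > 1)
    return out
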