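"""Synthetic data generator for the wax-trait / g_c analysis pipeline.

Emulates a diversity panel of ~300 maize inbred lines: dosage genotypes with
linkage disequilibrium and population structure, non-overlapping gene models,
cis-regulated gene expression with latent confounders, six classes of
correlated, zero-inflated cuticular-wax traits measured in a two-environment
field trial with laboratory (GC-FID) nuisance effects, and a cuticular
conductance (g_c) phenotype driven by the genetic values of a small subset of
wax traits.  Every simulation returns a machine-readable truth record so that
downstream estimators can be tested for parameter recovery.

All functions are deterministic given their ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import WAX_CLASSES, derive_seed

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeLayout:
    """Chromosome lengths and sorted, non-overlapping gene models.

    Coordinates are 1-based inclusive (GFF3 convention).
    """

    chrom_lengths: list[tuple[str, int]]
    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def validate(self) -> None:
        lengths = dict(self.chrom_lengths)
        g = self.genes
        if (g["start"] > g["end"]).any():
            raise ValueError("gene start > end")
        for chrom, sub in g.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"gene on unknown chromosome {chrom}")
            if (sub["start"] < 1).any() or (sub["end"] > lengths[chrom]).any():
                raise ValueError(f"gene outside chromosome bounds on {chrom}")
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping genes on {chrom}")


@dataclass
class GenotypeMatrix:
    """Line x SNP dosage matrix with per-SNP metadata.

    ``dosages`` holds values in {0, 1, 2}; an inbred panel is emitted as
    homozygous {0, 2} dosages unless a heterozygosity rate is requested.
    ``snp_meta`` has columns snp_id, chrom, pos, maf, dr2 with positions
    strictly increasing within each chromosome and ``maf`` equal to the
    realized minor-allele frequency of ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages outside {0,1,2}")
        maf = realized_maf(self.dosages)
        if np.abs(maf - self.snp_meta["maf"].to_numpy()).max() > 1e-12:
            raise ValueError("stored MAF does not match dosages")
        for _, sub in self.snp_meta.groupby("chrom", sort=False):
            if not (np.diff(sub["pos"].to_numpy()) > 0).all():
                raise ValueError("positions not strictly increasing")


@dataclass
class TruthRecord:
    """Ground truth of a simulation, consumed only by tests and benchmarks."""

    causal_snps: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    causal_genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    variance_components: dict[str, dict[str, float]] = field(default_factory=dict)
    gc_weights: dict[str, float] = field(default_factory=dict)
    gc_noise_sd: float = 0.0
    seed: int | None = None
    # extras useful for parameter-recovery checks
    genetic_values: pd.DataFrame | None = None  # line x trait latent genetic value
    gc_genetic: pd.Series | None = None
    cis_assignments: pd.DataFrame | None = None  # gene_id, snp_index, beta, has_cis
    implied_h2: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "causal_snps": {t: [[int(i), float(b)] for i, b in v] for t, v in self.causal_snps.items()},
            "causal_genes": {t: [[g, float(b)] for g, b in v] for t, v in self.causal_genes.items()},
            "variance_components": self.variance_components,
            "gc_weights": {t: float(w) for t, w in self.gc_weights.items()},
            "gc_noise_sd": float(self.gc_noise_sd),
            "seed": self.seed,
            "implied_h2": {t: float(h) for t, h in self.implied_h2.items()},
        }


def realized_maf(dosages: np.ndarray) -> np.ndarray:
    f = dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def simulate_population(
    n_lines: int = 300,
    n_snps: int = 5000,
    chrom_lengths: Sequence[tuple[str, int]] = (("1", 100_000_000), ("2", 100_000_000)),
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay_bp: float = 200_000.0,
    n_subpops: int = 1,
    fst: float = 0.0,
    het_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate an inbred-panel dosage matrix with LD and population structure.

    LD is induced by an autoregressive Gaussian copula over the ordered SNP
    positions: the latent correlation between adjacent SNPs decays as
    exp(-distance / ld_decay_bp).  Population structure follows the
    Balding-Nichols model: subpopulation allele frequencies are Beta-distributed
    around the ancestral frequency with divergence controlled by ``fst``.
    SNPs whose realized MAF drifts outside ``maf_range`` are re-thresholded
    (new target frequency, same latent field) until the contract holds.
    DR2 is set to 1.0 (no imputation is simulated).
    """
    if n_lines < 2 or n_snps < 1:
        raise ValueError("n_lines must be >= 2 and n_snps >= 1")
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")
    if ld_decay_bp <= 0:
        raise ValueError("ld_decay_bp must be positive")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")

    rng = np.random.default_rng(seed)
    chrom_lengths = list(chrom_lengths)
    total_len = sum(L for _, L in chrom_lengths)

    # allot SNPs to chromosomes proportionally to length
    counts = [int(round(n_snps * L / total_len)) for _, L in chrom_lengths]
    counts[-1] += n_snps - sum(counts)

    chroms, positions = [], []
    for (chrom, L), k in zip(chrom_lengths, counts):
        if k == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=k, replace=False))
        chroms.extend([chrom] * k)
        positions.append(pos)
    positions = np.concatenate(positions)
    chroms = np.asarray(chroms)

    subpop = rng.integers(0, n_subpops, size=n_lines)

    # latent AR(1) field per line, restarted at chromosome boundaries
    z = np.empty((n_lines, n_snps))
    start = 0
    for (chrom, _), k in zip(chrom_lengths, counts):
        if k == 0:
            continue
        pos = positions[start : start + k]
        rho = np.exp(-np.diff(pos) / ld_decay_bp)
        zc = np.empty((n_lines, k))
        zc[:, 0] = rng.standard_normal(n_lines)
        eps = rng.standard_normal((n_lines, k - 1)) if k > 1 else None
        for j in range(1, k):
            zc[:, j] = rho[j - 1] * zc[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * eps[:, j - 1]
        z[:, start : start + k] = zc
        start += k

    def draw_freqs(n: int) -> tuple[np.ndarray, np.ndarray]:
        p_anc = rng.uniform(lo, hi, size=n)
        if n_subpops > 1 and fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_sub = np.clip(rng.beta(a[None, :], b[None, :], size=(n_subpops, n)), 1e-4, 1 - 1e-4)
        else:
            p_sub = np.tile(p_anc, (n_subpops, 1))
        return p_anc, p_sub

    _, p_sub = draw_freqs(n_snps)
    thresh = stats.norm.ppf(p_sub)  # (n_subpops, n_snps)
    allele = (z < thresh[subpop, :]).astype(np.int8)
    dos = 2 * allele
    if het_rate > 0:
        # second, independent allele at a het_rate fraction of entries
        mask = rng.random((n_lines, n_snps)) < het_rate
        second = (rng.random((n_lines, n_snps)) < p_sub[subpop, :]).astype(np.int8)
        dos = np.where(mask, allele + second, dos).astype(np.int8)

    # finite-sample drift correction: re-threshold violators until MAF in range
    for _ in range(200):
        maf = realized_maf(dos)
        bad = (maf < lo) | (maf > hi)
        if not bad.any():
            break
        nb = int(bad.sum())
        _, p_new = draw_freqs(nb)
        thr = stats.norm.ppf(p_new)
        allele_b = (z[:, bad] < thr[subpop, :]).astype(np.int8)
        dos[:, bad] = 2 * allele_b
    else:
        raise RuntimeError("could not satisfy maf_range after 200 resampling rounds")

    maf = realized_maf(dos)
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"snp_{c}_{p}" for c, p in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions.astype(np.int64),
            "maf": maf,
            "dr2": np.ones(n_snps),
        }
    )
    line_ids = [f"L{i:04d}" for i in range(n_lines)]
    gm = GenotypeMatrix(dosages=dos.astype(np.int8), snp_meta=snp_meta, line_ids=line_ids)
    gm.subpop = subpop  # attribute for structure-aware tests
    return gm


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def simulate_gene_models(
    n_genes: int = 400,
    chrom_lengths: Sequence[tuple[str, int]] = (("1", 100_000_000), ("2", 100_000_000)),
    min_len: int = 2000,
    max_len: int = 6000,
    seed: int = 0,
) -> GenomeLayout:
    """Place non-overlapping gene intervals uniformly along the chromosomes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    rng = np.random.default_rng(seed)
    chrom_lengths = list(chrom_lengths)
    total_len = sum(L for _, L in chrom_lengths)
    counts = [int(round(n_genes * L / total_len)) for _, L in chrom_lengths]
    counts[-1] += n_genes - sum(counts)

    rows = []
    gi = 0
    for (chrom, L), k in zip(chrom_lengths, counts):
        if k == 0:
            continue
        lens = rng.integers(min_len, max_len + 1, size=k)
        slack = L - int(lens.sum())
        if slack < 0:
            raise ValueError(f"genes cannot fit on chromosome {chrom} without overlap")
        # distribute the free space as k+1 random gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 1
        for length, gap in zip(lens, gaps):
            start = pos + int(gap)
            end = start + int(length) - 1
            rows.append((f"gene_{gi:05d}", chrom, start, end, "+" if rng.random() < 0.5 else "-"))
            pos = end + 2  # at least 1 bp between genes
            gi += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    layout = GenomeLayout(chrom_lengths=chrom_lengths, genes=genes)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSim:
    """Simulated expression: per-environment line x gene matrices plus truth."""

    values: np.ndarray  # (n_lines, n_genes, n_envs)
    gene_ids: list[str]
    line_ids: list[str]
    genetic: np.ndarray  # (n_lines, n_genes) cis genetic value
    truth: TruthRecord

    def line_means(self) -> pd.DataFrame:
        """Across-environment mean expression (simple stand-in for BLUPs)."""
        return pd.DataFrame(self.values.mean(axis=2), index=self.line_ids, columns=self.gene_ids)


def simulate_expression(
    genotypes: GenotypeMatrix,
    layout: GenomeLayout,
    cis_window_bp: int = 50_000,
    cis_h2: float = 0.4,
    n_latent_factors: int = 5,
    factor_h2: float = 0.3,
    n_envs: int = 2,
    noise_sd: float | None = None,
    seed: int = 0,
) -> ExpressionSim:
    """Simulate cis-regulated expression with shared latent confounders.

    Each gene's latent expression is ``beta * cis_dosage + loadings . factors``
    with a per-(line, env) residual; environments share the genetic and factor
    contributions.  The cis SNP is drawn among SNPs within ``cis_window_bp``
    of the gene interval; a gene with no SNP in its window gets a zero cis
    effect and is flagged in the truth record.  Variance shares are cis_h2 for
    the cis term and factor_h2 for the confounders (when factors are present);
    the residual absorbs the remainder unless ``noise_sd`` is given.
    """
    if not (0.0 <= cis_h2 < 1.0):
        raise ValueError("cis_h2 must lie in [0, 1)")
    if n_latent_factors < 0:
        raise ValueError("n_latent_factors must be >= 0")
    rng = np.random.default_rng(seed)
    n_lines = genotypes.n_lines
    genes = layout.genes
    n_genes = len(genes)

    fshare = factor_h2 if n_latent_factors > 0 else 0.0
    if noise_sd is None:
        noise_sd = float(np.sqrt(max(1.0 - cis_h2 - fshare, 0.0)))

    pos = genotypes.snp_meta["pos"].to_numpy()
    chrom = genotypes.snp_meta["chrom"].to_numpy()

    genetic = np.zeros((n_lines, n_genes))
    cis_rows = []
    for gi, row in enumerate(genes.itertuples(index=False)):
        on_chrom = np.flatnonzero(chrom == row.chrom)
        if on_chrom.size:
            d = np.maximum(row.start - pos[on_chrom], pos[on_chrom] - row.end)
            near = on_chrom[d <= cis_window_bp]
        else:
            near = np.array([], dtype=int)
        if cis_h2 > 0 and near.size:
            j = int(rng.choice(near))
            x = genotypes.dosages[:, j].astype(float)
            sd = x.std()
            xs = (x - x.mean()) / sd if sd > 0 else np.zeros(n_lines)
            genetic[:, gi] = np.sqrt(cis_h2) * xs
            cis_rows.append((row.gene_id, j, float(np.sqrt(cis_h2)), True))
        else:
            cis_rows.append((row.gene_id, -1, 0.0, False))

    if n_latent_factors > 0:
        factors = rng.standard_normal((n_lines, n_latent_factors))
        loadings = rng.standard_normal((n_latent_factors, n_genes))
        loadings *= np.sqrt(fshare / n_latent_factors)
        shared = factors @ loadings
    else:
        shared = np.zeros((n_lines, n_genes))

    values = np.empty((n_lines, n_genes, n_envs))
    for e in range(n_envs):
        values[:, :, e] = genetic + shared + noise_sd * rng.standard_normal((n_lines, n_genes))

    truth = TruthRecord(seed=seed)
    truth.cis_assignments = pd.DataFrame(cis_rows, columns=["gene_id", "snp_index", "beta", "has_cis"])
    truth.causal_genes = {}
    return ExpressionSim(
        values=values,
        gene_ids=genes["gene_id"].tolist(),
        line_ids=list(genotypes.line_ids),
        genetic=genetic,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Wax traits, field design and g_c
# ---------------------------------------------------------------------------

# Default compound panel: 53 compounds over the six wax classes, matching the
# class sizes of the adult-leaf panel (7 PA, 11 FA, 9 HC, 4 AD, 14 WE, 8 AC),
# plus one sum trait per class and the grand total = 60 traits.
_DEFAULT_CLASS_COUNTS = {"PA": 7, "FA": 11, "HC": 9, "AD": 4, "WE": 14, "AC": 8}

_AC_NAMES = ["Friedelin", "a-Amyrin", "b-Amyrin", "Unk1", "Unk2", "Unk3", "Unk4", "Unk5"]


def default_trait_registry(class_counts: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Registry of wax traits: compounds per class, class sums, and total wax.

    Returns a DataFrame with columns trait_id, wax_class, is_sum.  With the
    default class sizes this yields 53 compound traits and 60 traits in all.
    """
    counts = dict(class_counts or _DEFAULT_CLASS_COUNTS)
    rows = []
    chain_start = {"PA": 22, "FA": 16, "HC": 23, "AD": 24, "WE": 42}
    for cls in WAX_CLASSES:
        k = counts.get(cls, 0)
        for i in range(k):
            if cls == "AC":
                name = f"AC {_AC_NAMES[i % len(_AC_NAMES)]}" + ("" if i < len(_AC_NAMES) else f"_{i}")
            elif cls == "WE":
                name = f"WE {chain_start[cls] + i}:0"
            else:
                name = f"{cls} {chain_start[cls] + 2 * i}:0"
            rows.append((name, cls, False))
    for cls in WAX_CLASSES:
        if counts.get(cls, 0) > 0:
            rows.append((f"Total {cls}", cls, True))
    rows.append(("Total wax", "ALL", True))
    return pd.DataFrame(rows, columns=["trait_id", "wax_class", "is_sum"])


@dataclass
class ClassConfig:
    """How compounds map to classes and share causal loci within a class."""

    class_counts: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_CLASS_COUNTS))
    shared_frac: float = 0.45  # per-compound participation rate in each class-shared locus
    n_shared_loci: int = 6  # class-level shared causal SNPs (banded along the series)
    n_private_loci: int = 2  # per-compound private causal SNPs
    n_shared_genes: int = 1  # class-level shared causal expression genes
    n_private_genes: int = 1
    n_global_loci: int = 2  # panel-wide "wax flux" loci shared across classes
    global_frac: float = 0.6  # probability a compound picks up each global locus
    global_scale: float = 0.6  # effect-size scale of global loci vs class loci


@dataclass
class TraitTruthSpec:
    """Variance components (trait-SD units) and the g_c construction."""

    sigma2_G: float = 1.0
    sigma2_env: float = 0.2
    sigma2_GE: float = 0.3
    sigma2_block: float = 0.1
    sigma2_col: float = 0.05
    sigma2_instr: float = 0.05
    sigma2_instr_col: float = 0.05
    sigma2_resid: float = 0.5
    gc_weights: dict[str, float] | None = None  # trait -> weight; default: 6 WE/FA traits
    gc_noise_sd: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {
            "genotype": self.sigma2_G,
            "env": self.sigma2_env,
            "gxe": self.sigma2_GE,
            "block": self.sigma2_block,
            "col": self.sigma2_col,
            "instrument": self.sigma2_instr,
            "instr_col": self.sigma2_instr_col,
            "residual": self.sigma2_resid,
        }


@dataclass
class FieldDesign:
    """Two-environment augmented field trial with GC-FID lab structure."""

    n_envs: int = 2
    n_blocks_per_env: int = 8
    n_field_cols_per_env: int = 6
    plots_per_line_per_env: int = 1
    n_instruments: int = 2
    n_cols_per_instrument: int = 2


def simulate_traits_and_gc(
    genotypes: GenotypeMatrix,
    expression: ExpressionSim | None = None,
    layout: GenomeLayout | None = None,
    class_config: ClassConfig | None = None,
    truth_spec: TraitTruthSpec | None = None,
    field_design: FieldDesign | None = None,
    zero_rate_per_trait: Mapping[str, float] | float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate plot-level wax traits, class sums, total wax, and g_c.

    Compound abundances are built from causal-SNP effects (shared within a
    class at rate ``shared_frac``, driving within-class correlation) plus
    causal-gene expression effects, environment / GxE / block / field-column /
    instrument / instrument-column draws, and a residual; values are
    left-censored to 0 below a per-trait detection threshold chosen so that the
    requested fraction of lines falls entirely below it (mimicking limits of
    detection).  Class sums and total wax are the per-plot sums of the
    censored compound values.  g_c is a weighted sum of trait genetic values
    plus noise, emitted as its own plot table without censoring.

    Returns ``(wax_plot_table, gc_plot_table, truth)``.
    """
    cfg = class_config or ClassConfig()
    spec = truth_spec or TraitTruthSpec()
    fd = field_design or FieldDesign()
    rng = np.random.default_rng(seed)

    registry = default_trait_registry(cfg.class_counts)
    compounds = registry[~registry["is_sum"]]
    n_lines = genotypes.n_lines
    line_ids = list(genotypes.line_ids)

    X = genotypes.dosages.astype(float)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    if expression is not None:
        E = expression.genetic  # use the heritable part of expression
        Es = (E - E.mean(axis=0)) / np.where(E.std(axis=0) > 0, E.std(axis=0), 1.0)
        gene_ids = expression.gene_ids
    else:
        Es, gene_ids = None, []

    truth = TruthRecord(seed=seed, gc_noise_sd=spec.gc_noise_sd)
    genetic = {}
    # panel-wide flux loci: weak, same-direction effects across all classes,
    # giving compounds of different classes their modest background correlation
    global_snps = rng.choice(genotypes.n_snps, size=cfg.n_global_loci, replace=False)
    global_signs = rng.choice([-1.0, 1.0], size=cfg.n_global_loci)
    for cls, sub in compounds.groupby("wax_class", sort=False):
        shared_snps = rng.choice(genotypes.n_snps, size=cfg.n_shared_loci, replace=False)
        # a shared pathway locus pushes every compound of the class in the same
        # direction (co-regulated biosynthesis); private loci have free signs
        shared_signs = rng.choice([-1.0, 1.0], size=cfg.n_shared_loci)
        shared_genes = (
            rng.choice(len(gene_ids), size=min(cfg.n_shared_genes, len(gene_ids)), replace=False)
            if Es is not None and len(gene_ids)
            else np.array([], dtype=int)
        )
        shared_gene_signs = rng.choice([-1.0, 1.0], size=len(shared_genes))
        # each shared locus acts on a contiguous band of the class's
        # chain-length series: adjacent homologs share nearly the whole
        # elongation pathway, so they pick up more of the same loci than
        # distant members of the class do.  Band half-width and the extended
        # center range are chosen so each compound participates in a locus
        # with probability ~shared_frac, uniformly along the series.
        m_c = len(sub)
        f = min(cfg.shared_frac, 0.95)
        band_half = max(0.5, f * m_c / (2.0 * (1.0 - f)))
        band_centers = rng.uniform(-band_half, m_c - 1 + band_half, size=cfg.n_shared_loci)
        for ti, trait in enumerate(sub["trait_id"]):
            use = np.abs(ti - band_centers) <= band_half
            snps = [int(s) for s in shared_snps[use]]
            signs = list(shared_signs[use])
            priv = rng.choice(genotypes.n_snps, size=cfg.n_private_loci, replace=False)
            snps += [int(s) for s in priv]
            signs += list(rng.choice([-1.0, 1.0], size=len(priv)))
            effects = rng.uniform(0.4, 1.0, size=len(snps)) * np.asarray(signs)
            useG = rng.random(cfg.n_global_loci) < cfg.global_frac
            if useG.any():
                snps += [int(s) for s in global_snps[useG]]
                effects = np.concatenate(
                    [
                        effects,
                        cfg.global_scale
                        * rng.uniform(0.4, 1.0, size=int(useG.sum()))
                        * global_signs[useG],
                    ]
                )
            g = Xs[:, snps] @ effects if snps else np.zeros(n_lines)
            gene_list: list[tuple[str, float]] = []
            if Es is not None and len(gene_ids):
                useg = rng.random(len(shared_genes)) < cfg.shared_frac
                gs = [int(s) for s in shared_genes[useg]]
                gsign = list(shared_gene_signs[useg])
                privg = rng.choice(len(gene_ids), size=cfg.n_private_genes, replace=False)
                gs += [int(s) for s in privg]
                gsign += list(rng.choice([-1.0, 1.0], size=len(privg)))
                ge = rng.uniform(0.4, 1.0, size=len(gs)) * np.asarray(gsign)
                g = g + Es[:, gs] @ ge
                gene_list = [(gene_ids[i], float(b)) for i, b in zip(gs, ge)]
            sd = g.std()
            g = g / sd * np.sqrt(spec.sigma2_G) if sd > 0 else g
            genetic[trait] = g
            truth.causal_snps[trait] = [(int(s), float(b)) for s, b in zip(snps, effects)]
            truth.causal_genes[trait] = gene_list
            truth.variance_components[trait] = spec.as_dict()

    # ---- field / lab design draws (shared across traits within a plot) ----
    env_ids = np.arange(1, fd.n_envs + 1)
    rows_meta = []
    for e in env_ids:
        order = rng.permutation(n_lines)
        blocks = np.array_split(order, fd.n_blocks_per_env)
        for b, idxs in enumerate(blocks):
            for li in idxs:
                for _ in range(fd.plots_per_line_per_env):
                    col = rng.integers(1, fd.n_field_cols_per_env + 1)
                    instr = rng.integers(1, fd.n_instruments + 1)
                    icol = rng.integers(1, fd.n_cols_per_instrument + 1)
                    rows_meta.append((line_ids[li], int(li), int(e), b + 1, int(col), int(instr), int(icol)))
    meta = pd.DataFrame(
        rows_meta,
        columns=["line_id", "_li", "env", "block_id", "column_id", "instrument_id", "instrument_column_id"],
    )
    n_plots = len(meta)

    def effect_draws(keys: pd.Series, var: float) -> np.ndarray:
        levels, inv = np.unique(keys, return_inverse=True)
        draws = rng.normal(0.0, np.sqrt(var), size=len(levels))
        return draws[inv]

    trait_frames = []
    mu_shift = {}
    zero_rate = zero_rate_per_trait
    comp_values = {}
    for trait in compounds["trait_id"]:
        zr = zero_rate.get(trait, 0.0) if isinstance(zero_rate, Mapping) else float(zero_rate)
        g = genetic[trait]
        y = g[meta["_li"].to_numpy()]
        y = y + effect_draws(meta["env"], spec.sigma2_env)
        y = y + effect_draws(meta["env"].astype(str) + ":" + meta["line_id"], spec.sigma2_GE)
        y = y + effect_draws(meta["env"].astype(str) + ":" + meta["block_id"].astype(str), spec.sigma2_block)
        y = y + effect_draws(meta["env"].astype(str) + ":" + meta["column_id"].astype(str), spec.sigma2_col)
        y = y + effect_draws(meta["instrument_id"], spec.sigma2_instr)
        y = y + effect_draws(
            meta["instrument_id"].astype(str) + ":" + meta["instrument_column_id"].astype(str),
            spec.sigma2_instr_col,
        )
        y = y + rng.normal(0.0, np.sqrt(spec.sigma2_resid), size=n_plots)
        # shift to a positive abundance scale (µg/dm2)
        mu = 4.0 * np.sqrt(spec.sigma2_G + spec.sigma2_resid)
        y = y + mu
        mu_shift[trait] = mu
        # left-censor so that a fraction ~zr of lines is entirely below LOD
        if zr > 0:
            per_line_max = pd.Series(y).groupby(meta["_li"].to_numpy()).max()
            tau = float(np.quantile(per_line_max, zr))
        else:
            tau = 0.0
        y = np.where(y < max(tau, 0.0), 0.0, y)
        comp_values[trait] = y

    comp_df = pd.DataFrame(comp_values)
    # class sums and total from censored compound values (exact sums)
    for cls in WAX_CLASSES:
        cols = compounds.loc[compounds["wax_class"] == cls, "trait_id"]
        if len(cols):
            comp_df[f"Total {cls}"] = comp_df[cols].sum(axis=1)
    comp_df["Total wax"] = comp_df[compounds["trait_id"]].sum(axis=1)

    for trait in comp_df.columns:
        tf = meta.drop(columns="_li").copy()
        tf["trait_id"] = trait
        tf["value"] = comp_df[trait].to_numpy()
        trait_frames.append(tf)
    plot_table = pd.concat(trait_frames, ignore_index=True)
    cls_map = dict(zip(registry["trait_id"], registry["wax_class"]))
    plot_table["wax_class"] = plot_table["trait_id"].map(cls_map)
    plot_table["is_sum"] = plot_table["trait_id"].map(dict(zip(registry["trait_id"], registry["is_sum"])))
    plot_table["is_check"] = False

    # ---- g_c ----
    weights = spec.gc_weights
    if weights is None:
        # adjacent high-molecular-weight wax esters plus one free fatty acid,
        # mirroring the compounds most predictive of cuticular conductance
        we = [t for t in compounds.loc[compounds["wax_class"] == "WE", "trait_id"]][-5:]
        fa = [t for t in compounds.loc[compounds["wax_class"] == "FA", "trait_id"]]
        fa = [t for t in fa if t == "FA 22:0"] or fa[-1:]
        weights = {t: -0.5 for t in we} | {t: 0.5 for t in fa}
    unknown = set(weights) - set(genetic)
    if unknown:
        raise ValueError(f"g_c weight on unknown trait(s): {sorted(unknown)}")
    gc_gen = np.zeros(n_lines)
    for t, w in weights.items():
        gc_gen += w * genetic[t]
    gc_line = gc_gen + rng.normal(0.0, spec.gc_noise_sd, size=n_lines)
    gc_rows = meta.drop(columns="_li").drop_duplicates(["line_id", "env"]).copy()
    gc_rows["trait_id"] = "gc"
    li = [line_ids.index(l) for l in gc_rows["line_id"]]
    gc_rows["value"] = gc_line[li] + rng.normal(0.0, 0.1, size=len(gc_rows))
    gc_rows["is_check"] = False

    truth.gc_weights = {t: float(w) for t, w in weights.items()}
    truth.genetic_values = pd.DataFrame(genetic, index=line_ids)
    truth.gc_genetic = pd.Series(gc_gen, index=line_ids, name="gc_genetic")
    # implied line-mean heritability at this design (same formula as traitprep)
    e_bar = fd.n_envs
    r_bar = fd.n_envs * fd.plots_per_line_per_env
    for trait in genetic:
        truth.implied_h2[trait] = spec.sigma2_G / (
            spec.sigma2_G + spec.sigma2_GE / e_bar + spec.sigma2_resid / (e_bar * r_bar)
        )
    return plot_table, gc_rows, truth
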