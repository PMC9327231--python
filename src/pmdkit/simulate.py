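"""Synthetic paired-tumor WGBS cohort generator.

Emulates the statistical structure the pipeline assumes, so every stage is
testable without external data:

* a random genome with CpG-dense islands at gene TSSs, isolated
  WCGW-context CpGs between them, and a designated "PMD-capable" subset
  of 100 kb bins;
* per patient, a primary methylome whose solo-WCGW CpGs are hypomethylated
  inside that patient's planted PMDs (drawn from the capable bins) and
  highly methylated outside, with per-patient and per-bin PMD depth
  variation; non-solo CpGs near-fully methylated except island CpGs near 0;
* a recurrent methylome that is the primary plus a small Gaussian
  perturbation (strong intra-patient preservation), or an independent
  redraw for null calibrations;
* binomial read sampling: coverage ~ Binomial(n_r, p_r) per site and
  observed beta = Binomial(coverage, true beta) / coverage;
* planted DMRs in PMD-free space with per-patient methylation deltas and
  known concordance status;
* transcript-level expression with planted methylation-expression links
  at a target Spearman correlation.

A fixed :class:`CohortConfig` seed determines every output byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeSequence, classify_solo_wcgw, enumerate_cpgs, make_bins
from .intervals import IntervalSet
from .linking import TranscriptTable
from .methylome_io import MethylomeTable

__all__ = [
    "CohortConfig",
    "GenomeTruth",
    "SyntheticCohort",
    "simulate_genome",
    "simulate_cohort",
    "plant_dmrs",
    "simulate_expression",
]


@dataclass
class CohortConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_patients: int = 14
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    # sequence composition
    solo_spacing: int = 500          # mean bp between planted isolated WCGW CpGs
    background_cpg_keep: float = 0.05  # fraction of accidental CpGs retained
    n_genes: int = 120
    island_halfwidth: int = 300      # island = TSS +- halfwidth
    island_cpg_spacing: int = 8
    bin_width: int = 100_000
    pmd_capable_fraction: float = 0.4  # genome-level bins eligible to be PMD
    # methylation regimes (Beta distributions: mean, concentration)
    pmd_fraction_mean: float = 0.30
    pmd_fraction_sd: float = 0.05
    beta_in_pmd_mean: float = 0.55
    beta_in_pmd_conc: float = 20.0
    beta_out_mean: float = 0.88
    beta_out_conc: float = 40.0
    island_beta_mean: float = 0.08
    island_beta_conc: float = 30.0
    other_beta_mean: float = 0.85
    other_beta_conc: float = 40.0
    pmd_depth_sd: float = 0.10       # per-sample shift of the in-PMD mean
    pmd_bimodal_delta: float = 0.12  # deep vs shallow PMD bins: mean -+ delta
    pmd_bin_depth_sd: float = 0.04   # residual per-bin shift inside PMDs
    # read model
    coverage_reads: int = 40
    coverage_p: float = 0.75         # coverage ~ Binomial(40, 0.75), mean 30
    # pairing
    intra_patient_sd: float = 0.02
    independent_recurrent: bool = False  # exchangeable null: recurrent is a fresh draw
    carrier_fraction: float = 0.5
    carrier_offset: float = -0.25    # group-mode DMR effect in carriers
    # planted DMRs
    n_planted_dmrs: int = 30
    dmr_length_min: int = 500
    dmr_length_max: int = 2000
    dmr_effect: float = 0.30
    dmr_discordant_fraction: float = 0.3
    dmr_patients_min: int = 2
    dmr_patients_max: int = 5
    # expression
    link_fraction: float = 0.5
    link_rho: float = 0.7
    expr_baseline_mean: float = 5.0
    expr_baseline_sd: float = 1.5
    expr_noise_sd: float = 0.3

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class GenomeTruth:
    islands: IntervalSet
    tss: pd.DataFrame          # gene_id, chrom, tss, strand
    pmd_capable: IntervalSet   # union of PMD-eligible bins
    grid: BinGrid


@dataclass
class SyntheticCohort:
    config: CohortConfig
    genome: GenomeSequence
    truth: GenomeTruth
    sites: pd.DataFrame = field(repr=False)   # chrom, pos, is_solo_wcgw, in_island
    true_betas: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    samples: dict[str, MethylomeTable] = field(repr=False, default_factory=dict)
    truth_pmds: dict[str, IntervalSet] = field(repr=False, default_factory=dict)
    patient_of: dict[str, str] = field(default_factory=dict)
    sample_sheet: pd.DataFrame = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(cfg: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stage]))


def simulate_genome(cfg: CohortConfig) -> tuple[GenomeSequence, GenomeTruth]:
    rng = _rng(cfg, 1)
    sequences: dict[str, str] = {}
    island_records: list[tuple[str, int, int]] = []
    tss_rows = []
    sizes = cfg.chrom_sizes
    total = sum(sizes.values())
    gene_counter = 0
    for chrom, size in sizes.items():
        arr = rng.choice(_BASES, size=size, p=[0.3, 0.2, 0.2, 0.3])
        # thin out accidental CpGs so planted structure dominates
        hits = np.nonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))[0]
        kill = hits[rng.random(hits.size) >= cfg.background_cpg_keep]
        arr[kill + 1] = ord("A")
        # genes with CpG islands at their TSSs
        n_genes_c = max(1, round(cfg.n_genes * size / total))
        margin = cfg.island_halfwidth + 100
        anchors = np.linspace(margin, size - margin, n_genes_c)
        jitter = rng.integers(-2000, 2001, size=n_genes_c)
        tss_pos = np.clip(anchors.astype(np.int64) + jitter, margin, size - margin)
        for t in np.sort(tss_pos):
            t = int(t)
            lo, hi = t - cfg.island_halfwidth, t + cfg.island_halfwidth
            for p in range(lo, hi - 1, cfg.island_cpg_spacing):
                arr[p] = ord("C")
                arr[p + 1] = ord("G")
            island_records.append((chrom, lo, hi))
            tss_rows.append(
                (f"g{gene_counter:04d}", chrom, t, "+" if rng.random() < 0.5 else "-")
            )
            gene_counter += 1
        # isolated WCGW-context CpGs between islands
        islands_c = [(s, e) for c, s, e in island_records if c == chrom]
        guard = 40  # > solo window so islands never disqualify a planted site
        pos = 100
        min_step = 80
        while pos + 3 < size - 100:
            near_island = any(s - guard <= pos <= e + guard for s, e in islands_c)
            if not near_island:
                arr[pos - 1] = ord("A")
                arr[pos] = ord("C")
                arr[pos + 1] = ord("G")
                arr[pos + 2] = ord("T")
            pos += min_step + int(rng.exponential(max(cfg.solo_spacing - min_step, 1)))
        sequences[chrom] = arr.tobytes().decode("ascii")
    genome = GenomeSequence(sequences)
    grid = make_bins(sizes, width=cfg.bin_width)
    full = grid.bins[~grid.bins["partial"]]
    n_capable = round(cfg.pmd_capable_fraction * len(full))
    pick = rng.choice(len(full), size=n_capable, replace=False)
    capable = IntervalSet.from_records(
        [
            (r.chrom, int(r.start), int(r.end))
            for r in full.iloc[np.sort(pick)].itertuples(index=False)
        ]
    )
    truth = GenomeTruth(
        islands=IntervalSet.from_records(island_records),
        tss=pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss", "strand"]),
        pmd_capable=capable,
        grid=grid,
    )
    return genome, truth


def _beta_draw(
    rng: np.random.Generator, mean: float | np.ndarray, conc: float, size: int
) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 0.02, 0.98)
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def simulate_cohort(
    cfg: CohortConfig,
    genome: GenomeSequence | None = None,
    truth: GenomeTruth | None = None,
) -> SyntheticCohort:
    """Simulate paired primary/recurrent methylomes for ``cfg.n_patients``."""
    if cfg.pmd_fraction_mean >= 1:
        raise ValueError("pmd_fraction must be < 1")
    if genome is None or truth is None:
        genome, truth = simulate_genome(cfg)
    rng = _rng(cfg, 2)
    sites = classify_solo_wcgw(enumerate_cpgs(genome), genome)
    in_island = np.zeros(len(sites), dtype=bool)
    for chrom, sub in sites.groupby("chrom", sort=False):
        in_island[sub.index] = truth.islands.contains_points(
            chrom, sub["pos"].to_numpy()
        )
    sites = sites.assign(in_island=in_island)
    n = len(sites)
    solo = sites["is_solo_wcgw"].to_numpy() & ~in_island

    # cohort-shared baseline true betas
    baseline = _beta_draw(rng, cfg.other_beta_mean, cfg.other_beta_conc, n)
    baseline[in_island] = _beta_draw(
        rng, cfg.island_beta_mean, cfg.island_beta_conc, int(in_island.sum())
    )
    baseline[solo] = _beta_draw(rng, cfg.beta_out_mean, cfg.beta_out_conc, int(solo.sum()))

    capable_rows = []
    mids = ((truth.grid.bins["start"] + truth.grid.bins["end"]) // 2).to_numpy()
    chroms_arr = truth.grid.bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms_arr):
        m = chroms_arr == chrom
        inside = truth.pmd_capable.contains_points(chrom, mids[m])
        capable_rows.extend(np.nonzero(m)[0][inside])
    capable_rows = np.asarray(capable_rows)
    genome_len = sum(genome.chrom_sizes.values())

    cohort = SyntheticCohort(config=cfg, genome=genome, truth=truth, sites=sites)
    carriers = max(1, round(cfg.carrier_fraction * cfg.n_patients))
    sheet_rows = []

    # solo-site indices per grid row, computed once
    solo_by_bin: dict[int, np.ndarray] = {}
    solo_sites = sites[solo]
    for chrom, sub in solo_sites.groupby("chrom", sort=False):
        bidx = truth.grid.bin_index(chrom, sub["pos"].to_numpy())
        for b in np.unique(bidx[bidx >= 0]):
            solo_by_bin[int(b)] = sub.index.to_numpy()[bidx == b]

    def draw_sample_betas() -> tuple[np.ndarray, IntervalSet]:
        """One sample's true betas: baseline with PMD hypomethylation planted."""
        frac = float(
            np.clip(
                rng.normal(cfg.pmd_fraction_mean, cfg.pmd_fraction_sd), 0.05, 0.6
            )
        )
        n_bins = min(
            int(round(frac * genome_len / cfg.bin_width)), capable_rows.size
        )
        chosen = rng.choice(capable_rows, size=n_bins, replace=False)
        bins = truth.grid.bins.iloc[np.sort(chosen)]
        pmds = IntervalSet.from_records(
            [(r.chrom, int(r.start), int(r.end)) for r in bins.itertuples(index=False)]
        )
        depth = float(np.clip(rng.normal(cfg.beta_in_pmd_mean, cfg.pmd_depth_sd), 0.35, 0.75))
        betas = baseline.copy()
        for b in np.sort(chosen):
            sub = solo_by_bin.get(int(b))
            if sub is None or sub.size == 0:
                continue
            # PMD hypomethylation is itself bimodal across bins (deep vs
            # shallow domains), giving the low/intermediate regimes the
            # mixture model separates from the methylated background
            mode = -cfg.pmd_bimodal_delta if rng.random() < 0.5 else cfg.pmd_bimodal_delta
            mu_bin = float(
                np.clip(depth + mode + rng.normal(0, cfg.pmd_bin_depth_sd), 0.25, 0.85)
            )
            betas[sub] = _beta_draw(rng, mu_bin, cfg.beta_in_pmd_conc, sub.size)
        return betas, pmds

    for i in range(cfg.n_patients):
        patient = f"pt{i + 1:02d}"
        status = "carrier" if i < carriers else "non-carrier"
        primary, pmds_p = draw_sample_betas()
        if cfg.independent_recurrent:
            recurrent, pmds_r = draw_sample_betas()
        else:
            recurrent = np.clip(
                primary + rng.normal(0, cfg.intra_patient_sd, size=n), 0.0, 1.0
            )
            pmds_r = pmds_p
        for timepoint, betas, pmds in (
            ("primary", primary, pmds_p),
            ("recurrent", recurrent, pmds_r),
        ):
            sid = f"{patient}_{'P' if timepoint == 'primary' else 'R'}"
            cohort.true_betas[sid] = betas
            cohort.truth_pmds[sid] = pmds
            cohort.patient_of[sid] = patient
            sheet_rows.append((sid, patient, timepoint, status))
            tbl = _observe(cfg, rng, sites, betas)
            tbl.sample_id = sid
            cohort.samples[sid] = tbl
    cohort.sample_sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "patient_id", "timepoint", "carrier_status"]
    )
    return cohort


def _observe(
    cfg: CohortConfig,
    rng: np.random.Generator,
    sites: pd.DataFrame,
    betas: np.ndarray,
    subset: np.ndarray | None = None,
) -> MethylomeTable:
    """Binomial read sampling of true betas into an observed methylome."""
    idx = np.arange(len(sites)) if subset is None else subset
    cov = rng.binomial(cfg.coverage_reads, cfg.coverage_p, size=idx.size)
    meth = rng.binomial(cov, betas[idx])
    keep = cov > 0
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[idx][keep],
            "pos": sites["pos"].to_numpy()[idx][keep],
            "beta": meth[keep] / cov[keep],
            "coverage": cov[keep].astype(np.int64),
        }
    )
    return MethylomeTable("tmp", df)


def _reobserve(
    cfg: CohortConfig,
    rng: np.random.Generator,
    cohort: SyntheticCohort,
    sample_id: str,
    site_idx: np.ndarray,
) -> None:
    """Re-sample observed records for ``site_idx`` after true betas changed."""
    new = _observe(cfg, rng, cohort.sites, cohort.true_betas[sample_id], site_idx)
    old = cohort.samples[sample_id].df
    touched = pd.MultiIndex.from_arrays(
        [cohort.sites["chrom"].to_numpy()[site_idx], cohort.sites["pos"].to_numpy()[site_idx]]
    )
    old_idx = pd.MultiIndex.from_frame(old[["chrom", "pos"]])
    kept = old[~old_idx.isin(touched)]
    merged = (
        pd.concat([kept, new.df], ignore_index=True)
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    cohort.samples[sample_id] = MethylomeTable(sample_id, merged)


def plant_dmrs(
    cfg: CohortConfig, cohort: SyntheticCohort, mode: str = "shared"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant DMRs in PMD-free space by shifting recurrent true betas.

    mode="shared": each DMR gets a delta in a random subset of >= 2
    patients, discordant (mixed signs) with probability
    ``dmr_discordant_fraction``.
    mode="graded": every patient gets a delta drawn uniformly from
    [-dmr_effect, +dmr_effect] (continuous spread, for link analyses).
    mode="group": both timepoints of carrier patients are shifted by
    ``carrier_offset`` (carrier vs non-carrier comparisons).

    Returns (per-patient DMR records in metilene-like layout, truth
    summary with intended status). Observed betas at affected sites are
    re-sampled from the shifted true betas.
    """
    if mode not in ("shared", "graded", "group"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = _rng(cfg, 3)
    pmd_union = IntervalSet()
    for ivs in cohort.truth_pmds.values():
        pmd_union = pmd_union.union(ivs)
    genome_ivs = IntervalSet.from_records(
        [(c, 0, s) for c, s in cohort.genome.chrom_sizes.items()]
    )
    free = genome_ivs.subtract(pmd_union)
    segments = [seg for seg in free if seg[2] - seg[1] >= cfg.dmr_length_max + 2]
    if not segments:
        raise ValueError("no PMD-free space to plant DMRs in")
    weights = np.asarray([s[2] - s[1] for s in segments], dtype=float)
    weights /= weights.sum()
    patients = sorted(set(cohort.patient_of.values()))

    placed = IntervalSet()
    records = []
    summary = []
    sites = cohort.sites
    attempts = 0
    planted = 0
    while planted < cfg.n_planted_dmrs and attempts < cfg.n_planted_dmrs * 50:
        attempts += 1
        length = int(rng.integers(cfg.dmr_length_min, cfg.dmr_length_max + 1))
        chrom, s0, e0 = segments[rng.choice(len(segments), p=weights)]
        if e0 - s0 - length <= 0:
            continue
        start = int(rng.integers(s0, e0 - length))
        end = start + length
        if placed.overlaps_interval(chrom, start, end):
            continue
        sub = sites.index[
            (sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)
        ].to_numpy()
        if sub.size < 2:
            continue
        placed = placed.union(IntervalSet.from_records([(chrom, start, end)]))
        if mode == "group":
            deltas = {
                p: cfg.carrier_offset
                for p in patients
                if _is_carrier(cohort, p)
            }
            status = "group"
        elif mode == "graded":
            deltas = {
                p: float(rng.uniform(-cfg.dmr_effect, cfg.dmr_effect)) for p in patients
            }
            status = "graded"
        else:
            k = int(
                rng.integers(
                    cfg.dmr_patients_min,
                    min(cfg.dmr_patients_max, len(patients)) + 1,
                )
            )
            chosen = list(rng.choice(patients, size=k, replace=False))
            if rng.random() < cfg.dmr_discordant_fraction and k >= 2:
                signs = np.ones(k)
                n_neg = int(rng.integers(1, k))
                signs[:n_neg] = -1
                rng.shuffle(signs)
                status = "discordant"
            else:
                signs = np.full(k, 1.0 if rng.random() < 0.5 else -1.0)
                status = "concordant-hyper" if signs[0] > 0 else "concordant-hypo"
            deltas = {
                p: float(s * cfg.dmr_effect * rng.uniform(0.8, 1.2))
                for p, s in zip(chosen, signs)
            }
        for p, d in deltas.items():
            targets = [f"{p}_R"] if mode != "group" else [f"{p}_P", f"{p}_R"]
            realized = d
            for sid in targets:
                old = cohort.true_betas[sid][sub].copy()
                new = np.clip(old + d, 0.02, 0.98)
                cohort.true_betas[sid][sub] = new
                if sid.endswith("_R"):
                    # clipping attenuates the shift near 0/1; record what
                    # actually happened so truth matches observable change
                    realized = float(np.mean(new - old))
                _reobserve(cfg, rng, cohort, sid, sub)
            records.append(
                (chrom, start, end, p, realized, 0.01, int(sub.size))
            )
        summary.append((chrom, start, end, status, len(deltas)))
        planted += 1
    rec_df = pd.DataFrame(
        records,
        columns=["chrom", "start", "end", "patient_id", "delta_meth", "q_value", "n_cpgs"],
    )
    sum_df = pd.DataFrame(
        summary, columns=["chrom", "start", "end", "status", "n_patients"]
    )
    return rec_df, sum_df


def _is_carrier(cohort: SyntheticCohort, patient: str) -> bool:
    sheet = cohort.sample_sheet
    return (
        sheet.loc[sheet["patient_id"] == patient, "carrier_status"].iloc[0] == "carrier"
    )


def observed_dmr_deltas(
    cohort: SyntheticCohort, dmrs: pd.DataFrame | list
) -> dict[tuple, dict[str, float]]:
    """Observed (recurrent - primary) mean beta per patient for each DMR.

    Accepts the truth summary frame or a list of (chrom, start, end).
    """
    regions = (
        [(r.chrom, int(r.start), int(r.end)) for r in dmrs.itertuples(index=False)]
        if isinstance(dmrs, pd.DataFrame)
        else list(dmrs)
    )
    patients = sorted(set(cohort.patient_of.values()))
    out: dict[tuple, dict[str, float]] = {}
    for chrom, start, end in regions:
        deltas = {}
        for p in patients:
            vals = {}
            for suffix in ("P", "R"):
                df = cohort.samples[f"{p}_{suffix}"].df
                sel = df[
                    (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)
                ]
                vals[suffix] = sel["beta"].mean() if len(sel) else np.nan
            if not (np.isnan(vals["P"]) or np.isnan(vals["R"])):
                deltas[p] = float(vals["R"] - vals["P"])
        out[(chrom, start, end)] = deltas
    return out


def simulate_expression(
    cfg: CohortConfig,
    cohort: SyntheticCohort,
    truth_dmrs: pd.DataFrame,
) -> tuple[TranscriptTable, pd.DataFrame]:
    """Transcript-level TPMs with planted methylation-expression links.

    A ``link_fraction`` subset of planted DMRs is linked to its nearest
    gene: per patient, the gene's recurrent-sample expression is shifted
    by a value rank-correlated (Gaussian copula at ``link_rho``) with the
    observed DMR methylation delta. Remaining genes carry independent
    noise only.
    """
    rng = _rng(cfg, 4)
    tss = cohort.truth.tss
    genes = list(tss["gene_id"])
    sample_ids = cohort.sample_ids
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, size=len(genes))
    log_expr = pd.DataFrame(
        baseline[:, None] + rng.normal(0, cfg.expr_noise_sd, size=(len(genes), len(sample_ids))),
        index=genes,
        columns=sample_ids,
    )

    regions = truth_dmrs[["chrom", "start", "end"]].drop_duplicates()
    n_links = int(round(cfg.link_fraction * len(regions)))
    deltas_of = observed_dmr_deltas(cohort, regions)
    # assign planted links in random order, one DMR per target gene: a gene
    # linked twice would have its planted signal overwritten
    order = rng.permutation(len(regions))
    nearest_gene = []
    for _, row in regions.iterrows():
        sub = tss[tss["chrom"] == row["chrom"]]
        if sub.empty:
            nearest_gene.append(None)
            continue
        d = np.abs(sub["tss"].to_numpy() - (int(row["start"]) + int(row["end"])) // 2)
        nearest_gene.append(str(sub["gene_id"].iloc[int(np.argmin(d))]))
    planted_idx: set[int] = set()
    used_genes: set[str] = set()
    for j in order:
        if len(planted_idx) >= n_links:
            break
        g = nearest_gene[j]
        if g is None or g in used_genes:
            continue
        planted_idx.add(int(j))
        used_genes.add(g)
    truth_links = []
    for j, (_, row) in enumerate(regions.iterrows()):
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        gene = nearest_gene[j]
        if gene is None:
            continue
        planted = j in planted_idx
        if planted:
            deltas = deltas_of[(chrom, start, end)]
            pts = sorted(deltas)
            x = np.asarray([deltas[p] for p in pts])
            ranks = pd.Series(x).rank().to_numpy()
            z = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
            noise = rng.normal(0, 1, size=len(pts))
            shift = cfg.link_rho * z + np.sqrt(1 - cfg.link_rho**2) * noise
            # the per-patient expression *change* is the copula draw itself,
            # so the realised rank correlation hits link_rho
            for p, s in zip(pts, shift):
                log_expr.loc[gene, f"{p}_R"] = log_expr.loc[gene, f"{p}_P"] + float(s)
        truth_links.append((chrom, start, end, gene, planted))

    # transcripts: 1-3 isoforms per gene with Dirichlet shares
    info_rows = []
    tpm_rows = []
    iso_rows = []
    t_ids = []
    for gi, g in enumerate(genes):
        t_count = int(rng.integers(1, 4))
        shares = rng.dirichlet(np.ones(t_count))
        tss_pos = int(tss.loc[tss["gene_id"] == g, "tss"].iloc[0])
        chrom = str(tss.loc[tss["gene_id"] == g, "chrom"].iloc[0])
        gene_linear = np.power(2.0, log_expr.loc[g].to_numpy())
        for ti in range(t_count):
            tid = f"{g}.t{ti + 1}"
            length = int(rng.integers(200, 3001))
            info_rows.append((tid, g, chrom, tss_pos, tss_pos + length, length))
            tpm_rows.append(gene_linear * shares[ti])
            iso_rows.append(np.full(len(sample_ids), shares[ti] * 100.0))
            t_ids.append(tid)
    info = pd.DataFrame(
        info_rows, columns=["transcript_id", "gene_id", "chrom", "start", "end", "length"]
    )
    tpm = pd.DataFrame(np.vstack(tpm_rows), index=t_ids, columns=sample_ids)
    tpm = tpm / tpm.sum(axis=0) * 1e6  # normalise to transcripts-per-million
    iso = pd.DataFrame(np.vstack(iso_rows), index=t_ids, columns=sample_ids)
    table = TranscriptTable(info=info, tpm=tpm, isoform_pct=iso)
    links = pd.DataFrame(
        truth_links, columns=["chrom", "start", "end", "gene_id", "planted"]
    )
    return table, links
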