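"""Synthetic cohort generator.

Builds a fully self-contained cohort — exome probe depth, gene expression,
pedigrees, SNP genotypes inside deletions, a population CNV frequency
database and a ground-truth table — with the statistical structure the
downstream analysis assumes:

* probe-level read counts with multiplicative low-rank batch structure
  (the nuisance signal SVD denoising should strip) and gamma-Poisson
  overdispersion;
* planted deletions/duplications that scale expected depth by copy/2,
  transmitted from a parent or arising de novo;
* dosage-responsive expression in which most, but not all, genes inside a
  CNV scale with copy number;
* Mendelian-consistent SNP genotypes across deletions in parent-child
  duos, so haplotype-based de novo inference has something to work on.

Everything is drawn from one seeded generator: a fixed ``SimConfig``
yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .filters import CommonCnvDb, CommonCnvRecord, PedigreeTable, SnpGenotypeTable

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The default is a desk-scale profile: 8 trios + 6 duos + 4 singletons
    (40 samples) over 2000 probes — large enough for the depth pipeline's
    statistics to behave, small enough to simulate in seconds.
    ``study_profile()`` returns the full 98/72/20 cohort mix instead.
    """

    n_trios: int = 8
    n_duos: int = 6
    n_singletons: int = 4
    n_probes: int = 2000
    n_chromosomes: int = 4
    probe_length_bp: int = 200
    probe_spacing_bp: int = 1000
    read_length_bp: int = 100
    mean_depth: float = 100.0
    n_batch_factors: int = 1
    batch_sd: float = 0.05
    depth_noise: float = 0.001  # gamma-multiplier variance (overdispersion)
    cnv_rate_per_sample: float = 1.5
    cnv_probe_span_range: tuple[int, int] = (5, 20)
    de_novo_fraction: float = 0.3
    common_cnv_fraction: float = 0.05
    copy_numbers: tuple[int, ...] = (1, 3)
    n_db_records: int = 20
    responder_fraction: float = 0.8
    expr_mean_range: tuple[float, float] = (20.0, 200.0)
    expr_cv: float = 0.1
    n_genes: int = 300
    gene_length_bp: int = 4000
    snp_density: int = 20  # genotyped sites per duo deletion
    genotype_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_trios, self.n_duos, self.n_singletons, self.n_probes,
            self.n_chromosomes, self.n_genes, self.n_batch_factors,
            self.n_db_records, self.snp_density,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        for name in ("de_novo_fraction", "common_cnv_fraction",
                     "responder_fraction", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.cnv_probe_span_range
        if lo < 1 or hi < lo:
            raise ValueError("cnv_probe_span_range must satisfy 1 <= min <= max")
        if self.n_probes and hi > self.n_probes // max(self.n_chromosomes, 1):
            raise ValueError(
                "max CNV span exceeds probes per chromosome; "
                "enlarge n_probes or shrink cnv_probe_span_range"
            )
        if any(c not in (0, 1, 3, 4) for c in self.copy_numbers):
            raise ValueError("copy numbers restricted to {0, 1, 3, 4}")
        if self.cnv_rate_per_sample < 0 or self.mean_depth < 0:
            raise ValueError("rates must be non-negative")

    @classmethod
    def study_profile(cls, **overrides) -> "SimConfig":
        """Cohort mix at the scale of the motivating study (98/72/20)."""
        params = dict(n_trios=98, n_duos=72, n_singletons=20)
        params.update(overrides)
        return cls(**params)

    @property
    def n_samples(self) -> int:
        return 3 * self.n_trios + 2 * self.n_duos + self.n_singletons


@dataclass(frozen=True)
class PlantedCnv:
    """One ground-truth copy-number event in one sample."""

    sample: str
    chrom: str
    start: int
    end: int
    probe_lo: int  # inclusive index into the probe map
    probe_hi: int  # inclusive
    copy: int
    origin: str  # maternal / paternal / de_novo / founder (parent's own copy)
    deleted_haplotype: str | None = None  # for deletions: which haplotype was lost
    from_common_db: bool = False

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)

    @property
    def type(self) -> str:
        return "del" if self.copy < 2 else "dup"

    @property
    def n_probes(self) -> int:
        return self.probe_hi - self.probe_lo + 1


@dataclass
class CohortTruth:
    """Ground truth emitted by the simulator for evaluation."""

    planted_cnvs: list[PlantedCnv]
    responder_genes: pd.Series  # gene_id -> bool, dosage-responsive flag
    batch_loadings: pd.DataFrame  # sample x factor matrix behind the batch signal

    def responders_for(self, cnv: PlantedCnv, gene_models: pd.DataFrame) -> list[str]:
        """Dosage-responsive genes overlapping one planted event."""
        g = gene_models
        hit = (
            (g["chrom"] == cnv.chrom)
            & (g["start"] < cnv.end)
            & (g["end"] > cnv.start)
        )
        ids = g.loc[hit, "gene_id"]
        return [gid for gid in ids if bool(self.responder_genes.get(gid, False))]


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus the truth to score against."""

    config: SimConfig
    samples: list[str]
    probe_map: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series
    expression: pd.DataFrame
    gene_models: pd.DataFrame
    pedigree: PedigreeTable
    common_db: CommonCnvDb
    genotypes: SnpGenotypeTable
    truth: CohortTruth

    def coverage(self) -> pd.DataFrame:
        """Per-target mean depth implied by counts and read length."""
        c = self.config
        return self.counts * (c.read_length_bp / c.probe_length_bp)


# ---------------------------------------------------------------- layout


def _build_probe_map(cfg: SimConfig) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_probes // cfg.n_chromosomes)
    per_chrom[: cfg.n_probes % cfg.n_chromosomes] += 1
    rows = []
    pid = 0
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        for j in range(n):
            start = j * cfg.probe_spacing_bp
            rows.append((chrom, start, start + cfg.probe_length_bp, f"probe_{pid:05d}"))
            pid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id"])


def _build_gene_models(cfg: SimConfig, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Genes tiled across the probed region so CNVs hit whole genes."""
    rows = []
    chrom_groups = list(probe_map.groupby("chrom", sort=False))
    n_chrom = len(chrom_groups)
    if n_chrom == 0 or cfg.n_genes == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
    per_chrom = np.full(n_chrom, cfg.n_genes // n_chrom)
    per_chrom[: cfg.n_genes % n_chrom] += 1
    gid = 0
    for (chrom, probes), n in zip(chrom_groups, per_chrom):
        span = int(probes["end"].max())
        stride = max(span // max(n, 1), cfg.gene_length_bp)
        for j in range(n):
            start = j * stride
            rows.append((chrom, start, start + cfg.gene_length_bp, f"gene_{gid:04d}"))
            gid += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _build_pedigree(cfg: SimConfig, rng: np.random.Generator):
    """Sample ids and family links; duos alternate which parent is present."""
    samples: list[str] = []
    rows = []
    for i in range(cfg.n_trios):
        p, m, f = f"T{i:03d}P", f"T{i:03d}M", f"T{i:03d}F"
        samples += [p, m, f]
        rows.append((p, m, f, rng.choice(["F", "M"])))
    for i in range(cfg.n_duos):
        p = f"D{i:03d}P"
        if i % 2 == 0:
            parent, mother, father = f"D{i:03d}M", f"D{i:03d}M", ""
        else:
            parent, mother, father = f"D{i:03d}F", "", f"D{i:03d}F"
        samples += [p, parent]
        rows.append((p, mother, father, rng.choice(["F", "M"])))
    for i in range(cfg.n_singletons):
        p = f"S{i:03d}P"
        samples.append(p)
        rows.append((p, "", "", rng.choice(["F", "M"])))
    table = pd.DataFrame(rows, columns=["proband", "mother", "father", "sex"])
    return samples, PedigreeTable(table)


def _build_common_db(cfg: SimConfig, probe_map: pd.DataFrame,
                     rng: np.random.Generator) -> CommonCnvDb:
    """Half the records are frequent (MAF >= 0.01, big study) — the ones
    the common filter should act on; the rest sit below one threshold."""
    records = []
    chrom_index = {c: g.index.to_numpy() for c, g in probe_map.groupby("chrom", sort=False)}
    chroms = list(chrom_index)
    lo_span, hi_span = cfg.cnv_probe_span_range
    for i in range(cfg.n_db_records):
        chrom = chroms[int(rng.integers(len(chroms)))]
        idx = chrom_index[chrom]
        span = int(rng.integers(lo_span, hi_span + 1))
        span = min(span, len(idx))
        lo = int(rng.integers(0, len(idx) - span + 1))
        start = int(probe_map.at[idx[lo], "start"])
        end = int(probe_map.at[idx[lo + span - 1], "end"])
        if i % 2 == 0:
            maf, study_n = float(rng.uniform(0.01, 0.10)), int(rng.integers(50, 500))
        elif i % 4 == 1:
            maf, study_n = float(rng.uniform(0.0001, 0.005)), int(rng.integers(50, 500))
        else:
            maf, study_n = float(rng.uniform(0.01, 0.10)), int(rng.integers(5, 40))
        records.append(CommonCnvRecord(chrom, start, end, maf, study_n))
    return CommonCnvDb(records)


# ---------------------------------------------------------------- planting


def _plant_cnvs(cfg: SimConfig, probe_map: pd.DataFrame, pedigree: PedigreeTable,
                db: CommonCnvDb, rng: np.random.Generator) -> list[PlantedCnv]:
    chrom_probes = {c: g.index.to_numpy() for c, g in probe_map.groupby("chrom", sort=False)}
    chroms = list(chrom_probes)
    weights = np.array([len(chrom_probes[c]) for c in chroms], dtype=float)
    weights /= weights.sum() if weights.sum() else 1.0
    frequent = [r for r in db.records if r.maf >= 0.01 and r.study_n > 40]
    probe_starts = probe_map["start"].to_numpy()
    probe_ends = probe_map["end"].to_numpy()
    chrom_arr = probe_map["chrom"].to_numpy()
    lo_span, hi_span = cfg.cnv_probe_span_range

    # Independently placed events never share probes across samples: at desk
    # cohort sizes a second carrier inflates a probe's cross-sample sd enough
    # to mask both events, which real cohorts dilute over hundreds of samples.
    # Deliberate recurrence (common-database loci, inherited events) is exempt.
    occupied: dict[str, list[tuple[int, int]]] = {}
    occupied_global: list[tuple[int, int]] = []

    def free(sample: str, lo: int, hi: int) -> bool:
        return all(hi < a or lo > b for a, b in occupied.get(sample, []))

    def free_global(lo: int, hi: int) -> bool:
        return all(hi < a or lo > b for a, b in occupied_global)

    def claim(sample: str, lo: int, hi: int) -> None:
        occupied.setdefault(sample, []).append((lo, hi))

    planted: list[PlantedCnv] = []
    for proband in pedigree.probands:
        mother, father = pedigree.parents_of(proband)
        for _ in range(rng.poisson(cfg.cnv_rate_per_sample)):
            placed = None
            from_db = False
            for _attempt in range(20):
                if frequent and rng.random() < cfg.common_cnv_fraction:
                    rec = frequent[int(rng.integers(len(frequent)))]
                    idx = chrom_probes[rec.chrom]
                    in_rec = idx[(probe_starts[idx] >= rec.start) & (probe_ends[idx] <= rec.end)]
                    if len(in_rec) == 0:
                        continue
                    lo, hi = int(in_rec[0]), int(in_rec[-1])
                    from_db = True
                else:
                    chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                    idx = chrom_probes[chrom]
                    span = int(rng.integers(lo_span, min(hi_span, len(idx)) + 1))
                    off = int(rng.integers(0, len(idx) - span + 1))
                    lo, hi = int(idx[off]), int(idx[off + span - 1])
                    from_db = False
                if free(proband, lo, hi) and (from_db or free_global(lo, hi)):
                    placed = (lo, hi)
                    break
            if placed is None:
                continue
            lo, hi = placed
            copy = int(rng.choice(list(cfg.copy_numbers)))
            cnv_type = "del" if copy < 2 else "dup"

            if (mother or father) and rng.random() >= cfg.de_novo_fraction:
                origin = "maternal" if rng.random() < 0.5 else "paternal"
            else:
                origin = "de_novo"
            parent_id = {"maternal": mother, "paternal": father}.get(origin)
            if origin != "de_novo" and parent_id is not None and not free(parent_id, lo, hi):
                continue  # parent locus already taken; drop the event

            deleted_hap = None
            if cnv_type == "del":
                if origin in ("maternal", "paternal"):
                    deleted_hap = origin
                else:
                    deleted_hap = "maternal" if rng.random() < 0.5 else "paternal"

            claim(proband, lo, hi)
            if not from_db:
                occupied_global.append((lo, hi))
            planted.append(
                PlantedCnv(
                    sample=proband,
                    chrom=str(chrom_arr[lo]),
                    start=int(probe_starts[lo]),
                    end=int(probe_ends[hi]),
                    probe_lo=lo,
                    probe_hi=hi,
                    copy=copy,
                    origin=origin,
                    deleted_haplotype=deleted_hap,
                    from_common_db=from_db,
                )
            )
            if origin != "de_novo" and parent_id is not None:
                claim(parent_id, lo, hi)
                planted.append(
                    PlantedCnv(
                        sample=parent_id,
                        chrom=str(chrom_arr[lo]),
                        start=int(probe_starts[lo]),
                        end=int(probe_ends[hi]),
                        probe_lo=lo,
                        probe_hi=hi,
                        copy=copy,
                        origin="founder",
                        deleted_haplotype=None,
                        from_common_db=from_db,
                    )
                )
    return planted


# ---------------------------------------------------------------- matrices


def _copy_factor(cfg: SimConfig, planted: list[PlantedCnv],
                 samples: list[str]) -> np.ndarray:
    """Probe x sample matrix of copy/2 expectation scalings."""
    factor = np.ones((cfg.n_probes, len(samples)))
    col = {s: i for i, s in enumerate(samples)}
    for cnv in planted:
        factor[cnv.probe_lo : cnv.probe_hi + 1, col[cnv.sample]] = cnv.copy / 2.0
    return factor


def _simulate_depth(cfg: SimConfig, factor: np.ndarray, samples: list[str],
                    rng: np.random.Generator):
    n_p, n_s = cfg.n_probes, len(samples)
    loadings = rng.standard_normal((n_s, cfg.n_batch_factors))
    probe_factors = rng.standard_normal((cfg.n_batch_factors, n_p))
    log_batch = cfg.batch_sd * (loadings @ probe_factors).T  # probe x sample
    lam = cfg.mean_depth * np.exp(log_batch) * factor
    if cfg.depth_noise > 0:
        gamma = rng.gamma(1.0 / cfg.depth_noise, cfg.depth_noise, size=lam.shape)
        lam = lam * gamma
    counts = rng.poisson(lam).astype(np.int64)
    return counts, loadings


def _simulate_expression(cfg: SimConfig, gene_models: pd.DataFrame,
                         planted: list[PlantedCnv], samples: list[str],
                         rng: np.random.Generator):
    n_g, n_s = len(gene_models), len(samples)
    means = rng.uniform(*cfg.expr_mean_range, size=n_g)
    responder = rng.random(n_g) < cfg.responder_fraction
    factor = np.ones((n_g, n_s))
    col = {s: i for i, s in enumerate(samples)}
    g = gene_models
    for cnv in planted:
        hit = (
            (g["chrom"] == cnv.chrom) & (g["start"] < cnv.end) & (g["end"] > cnv.start)
        ).to_numpy()
        hit &= responder
        factor[hit, col[cnv.sample]] = cnv.copy / 2.0
    lam = means[:, None] * factor
    if cfg.expr_cv > 0 and lam.size:
        shape = 1.0 / cfg.expr_cv**2
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam).astype(np.int64)
    expr = pd.DataFrame(counts, index=g["gene_id"].to_numpy(), columns=samples)
    expr.index.name = "gene_id"
    resp = pd.Series(responder, index=g["gene_id"].to_numpy(), name="responder")
    return expr, resp


# ---------------------------------------------------------------- genotypes


def _simulate_genotypes(cfg: SimConfig, planted: list[PlantedCnv],
                        pedigree: PedigreeTable,
                        rng: np.random.Generator) -> SnpGenotypeTable:
    """SNP genotypes across deletions in duo probands.

    The proband's remaining haplotype carries the allele transmitted by
    the parent who did NOT contribute the deleted haplotype; the
    genotyped parent's diploid genotype is emitted alongside. Genotypes
    are error-free unless ``genotype_error_rate`` > 0.
    """
    rows = []

    def maybe_err(allele: str) -> str:
        if cfg.genotype_error_rate > 0 and rng.random() < cfg.genotype_error_rate:
            return str(rng.choice(_BASES[_BASES != allele]))
        return allele

    for cnv in planted:
        if cnv.copy > 1 or cnv.origin == "founder":
            continue
        if not pedigree.is_proband(cnv.sample):
            continue
        mother, father = pedigree.parents_of(cnv.sample)
        if (mother is None) == (father is None):
            continue  # only duos need haplotype evidence
        available = mother if mother is not None else father
        available_role = "maternal" if mother is not None else "paternal"
        if cfg.snp_density == 0:
            continue
        length = cnv.end - cnv.start
        positions = cnv.start + (
            (np.arange(cfg.snp_density) + 0.5) * length / cfg.snp_density
        ).astype(int)
        for pos in positions:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            freq = rng.uniform(0.2, 0.8)
            m_alleles = [ref if rng.random() < freq else alt for _ in range(2)]
            f_alleles = [ref if rng.random() < freq else alt for _ in range(2)]
            t_m = m_alleles[int(rng.integers(2))]
            t_f = f_alleles[int(rng.integers(2))]
            remaining = t_f if cnv.deleted_haplotype == "maternal" else t_m
            if cnv.copy == 1:
                rows.append((cnv.sample, cnv.chrom, int(pos), maybe_err(remaining)))
            parent_alleles = m_alleles if available_role == "maternal" else f_alleles
            pair = "/".join(sorted(maybe_err(a) for a in parent_alleles))
            rows.append((available, cnv.chrom, int(pos), pair))
    table = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "alleles"])
    return SnpGenotypeTable(table)


# ---------------------------------------------------------------- driver


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    probe_map = _build_probe_map(config)
    gene_models = _build_gene_models(config, probe_map)
    samples, pedigree = _build_pedigree(config, rng)
    common_db = _build_common_db(config, probe_map, rng)
    planted = _plant_cnvs(config, probe_map, pedigree, common_db, rng)
    factor = _copy_factor(config, planted, samples)
    counts_arr, loadings = _simulate_depth(config, factor, samples, rng)
    counts = pd.DataFrame(counts_arr, index=probe_map["probe_id"].to_numpy(), columns=samples)
    counts.index.name = "probe_id"
    totals = counts.sum(axis=0).astype(np.int64)
    totals.name = "total_reads"
    expression, responders = _simulate_expression(
        config, gene_models, planted, samples, rng
    )
    genotypes = _simulate_genotypes(config, planted, pedigree, rng)
    truth = CohortTruth(
        planted_cnvs=planted,
        responder_genes=responders,
        batch_loadings=pd.DataFrame(
            loadings, index=samples,
            columns=[f"factor_{k}" for k in range(config.n_batch_factors)],
        ),
    )
    return Cohort(
        config=config,
        samples=samples,
        probe_map=probe_map,
        counts=counts,
        totals=totals,
        expression=expression,
        gene_models=gene_models,
        pedigree=pedigree,
        common_db=common_db,
        genotypes=genotypes,
        truth=truth,
    )


def truth_to_calls(truth: CohortTruth):
    """Planted events as CnvCall objects (for matching against call sets)."""
    from .caller import CnvCall

    calls = []
    for cnv in truth.planted_cnvs:
        calls.append(
            CnvCall(
                sample=cnv.sample,
                chrom=cnv.chrom,
                start=cnv.start,
                end=cnv.end,
                type=cnv.type,
                n_probes=cnv.n_probes,
                mean_score=(cnv.copy - 2.0),
            )
        )
    return calls


# ---------------------------------------------------------------- writers

_FLOAT_FMT = "%.17g"


def _header(seed: int) -> str:
    return f"# dosecnv v{_version} seed={seed}\n"


def _write_table(df: pd.DataFrame, path: Path, seed: int, index: bool,
                 header: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=index, header=header,
                  float_format=_FLOAT_FMT)


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> dict:
    """Write every cohort artifact as BED/TSV/JSON; returns the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed

    files = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        # BED files carry no column header; TSV matrices/tables do
        _write_table(df, out / name, seed, index,
                     header=not name.endswith(".bed"))
        files[name.split(".")[0]] = name

    save("probes.bed", cohort.probe_map)
    save("genes.bed", cohort.gene_models)
    save("depth_counts.tsv", cohort.counts, index=True)
    save("totals.tsv", cohort.totals.to_frame(), index=True)
    save("expression_counts.tsv", cohort.expression, index=True)
    save("pedigree.tsv", cohort.pedigree.table)
    save("common_cnvs.bed", cohort.common_db.to_frame())
    save("genotypes.tsv", cohort.genotypes.table)
    truth_df = pd.DataFrame(
        [
            (c.sample, c.chrom, c.start, c.end, c.probe_lo, c.probe_hi, c.copy,
             c.origin, c.deleted_haplotype or "", int(c.from_common_db))
            for c in cohort.truth.planted_cnvs
        ],
        columns=["sample", "chrom", "start", "end", "probe_lo", "probe_hi",
                 "copy", "origin", "deleted_haplotype", "from_common_db"],
    )
    save("truth_cnvs.tsv", truth_df)
    save("responder_genes.tsv", cohort.truth.responder_genes.to_frame(), index=True)
    save("batch_loadings.tsv", cohort.truth.batch_loadings, index=True)

    manifest = {
        "tool": "dosecnv",
        "version": _version,
        "seed": seed,
        "n_samples": len(cohort.samples),
        "config": asdict(cohort.config),
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def read_cohort(in_dir) -> Cohort:
    """Round-trip reader for a directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("cnv_probe_span_range", "expr_mean_range", "copy_numbers"):
        cfg_dict[key] = tuple(
            (float(x) if key == "expr_mean_range" else int(x))
            for x in _parse_tuple(cfg_dict[key])
        )
    config = SimConfig(**cfg_dict)

    from . import io as dio

    def load(name: str, index_col=None) -> pd.DataFrame:
        return pd.read_csv(src / name, sep="\t", comment="#",
                           index_col=index_col)

    probe_map = dio.read_probe_map(src / "probes.bed")
    gene_models = dio.read_gene_models(src / "genes.bed")
    counts = load("depth_counts.tsv", index_col=0)
    totals = load("totals.tsv", index_col=0)["total_reads"]
    expression = load("expression_counts.tsv", index_col=0)
    pedigree = PedigreeTable(load("pedigree.tsv").fillna(""))
    common_db = CommonCnvDb.from_frame(
        dio.read_common_db_frame(src / "common_cnvs.bed"))
    geno = load("genotypes.tsv")
    if geno.empty:
        geno = pd.DataFrame(columns=["sample", "chrom", "pos", "alleles"])
    truth_df = load("truth_cnvs.tsv")
    planted = [
        PlantedCnv(
            sample=str(r.sample), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), probe_lo=int(r.probe_lo), probe_hi=int(r.probe_hi),
            copy=int(r.copy), origin=str(r.origin),
            deleted_haplotype=(str(r.deleted_haplotype)
                               if isinstance(r.deleted_haplotype, str)
                               and r.deleted_haplotype else None),
            from_common_db=bool(r.from_common_db),
        )
        for r in truth_df.itertuples()
    ]
    responders = load("responder_genes.tsv", index_col=0)["responder"].astype(bool)
    loadings = load("batch_loadings.tsv", index_col=0)
    samples = list(counts.columns)
    return Cohort(
        config=config,
        samples=samples,
        probe_map=probe_map,
        counts=counts,
        totals=totals,
        expression=expression,
        gene_models=gene_models,
        pedigree=pedigree,
        common_db=common_db,
        genotypes=SnpGenotypeTable(geno),
        truth=CohortTruth(planted, responders, loadings),
    )


def _parse_tuple(value):
    if isinstance(value, str):
        return [v for v in value.strip("()[] ").split(",") if v.strip()]
    return value
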