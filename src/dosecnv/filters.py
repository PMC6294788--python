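"""Population-frequency and cohort-recurrence filters, inheritance calls.

Calls are never removed: filters mark ``filter_status`` (`common` against a
population CNV database, `recurrent` within the cohort) and leave intervals
untouched, so stages can be re-run and audited. Inheritance is classified
against parental calls where parents exist; deletions in parent-child duos
can additionally be resolved by examining whether the remaining haplotype's
alleles could have come from the genotyped parent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .caller import CnvCall

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")


def overlap_fraction(a: tuple, b: tuple) -> tuple[float, float]:
    """Mutual coverage of two half-open intervals (chrom, start, end).

    Returns (fraction of a covered by b, fraction of b covered by a);
    (0, 0) for different chromosomes or disjoint intervals.
    """
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if end_a <= start_a or end_b <= start_b:
        raise ValueError("zero-length interval")
    if chrom_a != chrom_b:
        return 0.0, 0.0
    inter = min(end_a, end_b) - max(start_a, start_b)
    if inter <= 0:
        return 0.0, 0.0
    return inter / (end_a - start_a), inter / (end_b - start_b)


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min of the two mutual coverage fractions — the standard CNV match."""
    fa, fb = overlap_fraction(a, b)
    return min(fa, fb)


@dataclass(frozen=True)
class CommonCnvRecord:
    chrom: str
    start: int
    end: int
    maf: float
    study_n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("MAF must lie in [0, 1]")
        if self.study_n < 1:
            raise ValueError("study_n must be >= 1")
        if self.end <= self.start:
            raise ValueError("zero-length database interval")

    @property
    def interval(self) -> tuple:
        return (self.chrom, self.start, self.end)


class CommonCnvDb:
    """Population CNV frequency database (BED-like with MAF and study size)."""

    def __init__(self, records: list[CommonCnvRecord]):
        self.records = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
        self._trees: dict[str, IntervalTree] = {}
        for rec in self.records:
            self._trees.setdefault(rec.chrom, IntervalTree()).addi(
                rec.start, rec.end, rec
            )

    def __len__(self) -> int:
        return len(self.records)

    def overlapping(self, chrom: str, start: int, end: int) -> list[CommonCnvRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.maf, r.study_n) for r in self.records],
            columns=["chrom", "start", "end", "maf", "study_n"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CommonCnvDb":
        return cls(
            [
                CommonCnvRecord(
                    str(r.chrom), int(r.start), int(r.end), float(r.maf), int(r.study_n)
                )
                for r in df.itertuples()
            ]
        )


def filter_common(
    calls: list[CnvCall],
    db: CommonCnvDb,
    min_overlap: float = 0.8,
    min_maf: float = 0.01,
    min_study_n: int = 40,
    reciprocal: bool = False,
) -> list[CnvCall]:
    """Mark calls matching frequent population CNVs as `common`.

    A call is `common` when a database record with MAF >= ``min_maf`` from
    a study of more than ``min_study_n`` individuals covers at least
    ``min_overlap`` of the call. The default is one-way (fraction of the
    call), so a small call inside a large common CNV is flagged;
    ``reciprocal=True`` requires the mutual criterion instead. Input order
    is preserved and nothing is removed.
    """
    for call in calls:
        hit = False
        for rec in db.overlapping(call.chrom, call.start, call.end):
            if rec.maf < min_maf or rec.study_n <= min_study_n:
                continue
            frac_call, frac_rec = overlap_fraction(
                (call.chrom, call.start, call.end), rec.interval
            )
            covered = min(frac_call, frac_rec) if reciprocal else frac_call
            if covered >= min_overlap:
                hit = True
                break
        if hit:
            call.filter_status = "common"
    return calls


def _cluster_calls(calls: list[CnvCall], cluster_overlap: float) -> list[list[int]]:
    """Single-linkage clusters of same-type calls at >= reciprocal overlap."""
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    order = sorted(range(n), key=lambda i: (calls[i].chrom, calls[i].start))
    for a_pos, i in enumerate(order):
        ci = calls[i]
        for j in order[a_pos + 1 :]:
            cj = calls[j]
            if cj.chrom != ci.chrom or cj.start >= ci.end:
                break
            if cj.type != ci.type:
                continue
            ro = reciprocal_overlap(
                (ci.chrom, ci.start, ci.end), (cj.chrom, cj.start, cj.end)
            )
            if ro >= cluster_overlap:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def filter_recurrent(
    calls: list[CnvCall],
    pedigree: "PedigreeTable | None" = None,
    max_carriers: int = 10,
    cluster_overlap: float = 0.5,
) -> list[CnvCall]:
    """Mark cohort-recurrent loci (more than ``max_carriers`` individuals).

    Same-type calls are clustered by single-linkage at >= 50% reciprocal
    overlap; a cluster carried by more than ``max_carriers`` distinct
    individuals (probands and parents both count as carriers) marks all
    its calls `recurrent`. `common` status takes precedence and is never
    overwritten, which keeps the two filters order-independent.
    """
    for cluster in _cluster_calls(calls, cluster_overlap):
        carriers = {calls[i].sample for i in cluster}
        if len(carriers) > max_carriers:
            for i in cluster:
                if calls[i].filter_status == "pass":
                    calls[i].filter_status = "recurrent"
    return calls


@dataclass
class PedigreeTable:
    """Proband -> parent links; absent parents are None/empty."""

    table: pd.DataFrame  # columns: proband, mother, father, sex

    def __post_init__(self) -> None:
        required = {"proband", "mother", "father"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        self._rows = {
            str(r.proband): (
                str(r.mother) if _present(r.mother) else None,
                str(r.father) if _present(r.father) else None,
            )
            for r in self.table.itertuples()
        }

    def parents_of(self, proband: str) -> tuple[str | None, str | None]:
        """(mother id or None, father id or None)."""
        if proband not in self._rows:
            raise KeyError(f"{proband!r} is not a proband in the pedigree")
        return self._rows[proband]

    def is_proband(self, sample: str) -> bool:
        return sample in self._rows

    @property
    def probands(self) -> list[str]:
        return list(self._rows)


def _present(value) -> bool:
    return value is not None and not pd.isna(value) and str(value) not in ("", ".", "NA")


def classify_inheritance(
    proband_call: CnvCall,
    pedigree: PedigreeTable,
    all_calls: list[CnvCall],
    match_overlap: float = 0.5,
) -> str:
    """Label a proband call maternal/paternal/de_novo/unknown.

    A parental call of the same type matching at >= ``match_overlap``
    reciprocal overlap assigns that parent (mother first on a double
    match, logged). With both parents present and no match the call is
    de novo; with one or both parents missing and no match it stays
    unknown (duo deletions may later be upgraded by
    :func:`infer_denovo_deletion`).
    """
    mother, father = pedigree.parents_of(proband_call.sample)
    interval = (proband_call.chrom, proband_call.start, proband_call.end)

    def parent_has_match(parent: str | None) -> bool:
        if parent is None:
            return False
        for call in all_calls:
            if call.sample != parent or call.type != proband_call.type:
                continue
            if (
                reciprocal_overlap(interval, (call.chrom, call.start, call.end))
                >= match_overlap
            ):
                return True
        return False

    in_mother = parent_has_match(mother)
    in_father = parent_has_match(father)
    if in_mother and in_father:
        logger.info(
            "call %s %s:%d-%d matches both parents; assigning maternal",
            proband_call.sample,
            proband_call.chrom,
            proband_call.start,
            proband_call.end,
        )
        return "maternal"
    if in_mother:
        return "maternal"
    if in_father:
        return "paternal"
    if mother is not None and father is not None:
        return "de_novo"
    return "unknown"


@dataclass
class SnpGenotypeTable:
    """SNP genotypes at sites inside deletion regions.

    One row per (sample, site): ``alleles`` holds an unordered pair
    ("A/G") for diploid genotypes or a single base for a hemizygous
    sample whose other haplotype is deleted.
    """

    table: pd.DataFrame  # columns: sample, chrom, pos, alleles

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "pos", "alleles"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"genotype table needs columns {sorted(required)}")
        for g in self.table["alleles"]:
            if not set(str(g).split("/")) <= VALID_ALLELES:
                raise ValueError(f"invalid genotype {g!r}")

    def genotypes_in(self, sample: str, chrom: str, start: int, end: int) -> pd.Series:
        t = self.table
        sel = (
            (t["sample"] == sample)
            & (t["chrom"] == chrom)
            & (t["pos"] >= start)
            & (t["pos"] < end)
        )
        return t.loc[sel].set_index("pos")["alleles"]


def infer_denovo_deletion(
    del_call: CnvCall,
    available_parent_id: str,
    genotypes: SnpGenotypeTable,
    min_informative: int = 2,
) -> str:
    """Haplotype-based de novo inference for a deletion in a duo.

    The proband keeps one haplotype across the deletion; at each site the
    single remaining allele is compared with the genotyped parent. A site
    is *incompatible* when that parent is homozygous for a different
    allele — the remaining haplotype cannot derive from them, so the
    deleted haplotype must be the one they transmitted, and since they do
    not carry the deletion it arose de novo. At least ``min_informative``
    incompatible sites give `de_novo_inferred`; zero incompatible with
    >= ``min_informative`` compatible homozygous-parent sites place the
    deletion `on_missing_parent_haplotype` (inherited-or-de-novo on the
    ungenotyped parent's side); anything else is `ambiguous`.
    """
    if del_call.type != "del":
        raise ValueError("haplotype inference applies to deletions only")
    region = (del_call.chrom, del_call.start, del_call.end)
    proband_gt = genotypes.genotypes_in(del_call.sample, *region)
    parent_gt = genotypes.genotypes_in(available_parent_id, *region)
    if proband_gt.empty or parent_gt.empty:
        warnings.warn(
            f"no genotyped sites in {del_call.chrom}:{del_call.start}-{del_call.end}",
            RuntimeWarning,
            stacklevel=2,
        )
        return "ambiguous"

    incompatible = 0
    compatible_informative = 0
    for pos, proband_alleles in proband_gt.items():
        alleles = str(proband_alleles).split("/")
        if len(alleles) != 1:
            continue  # not hemizygous at this site
        remaining = alleles[0]
        if pos not in parent_gt.index:
            continue
        parent_alleles = set(str(parent_gt.loc[pos]).split("/"))
        if len(parent_alleles) != 1:
            continue  # heterozygous parent cannot exclude transmission
        if remaining in parent_alleles:
            compatible_informative += 1
        else:
            incompatible += 1

    if incompatible >= min_informative:
        return "de_novo_inferred"
    if incompatible == 0 and compatible_informative >= min_informative:
        return "on_missing_parent_haplotype"
    return "ambiguous"


def annotate_inheritance(
    calls: list[CnvCall],
    pedigree: PedigreeTable,
    genotypes: SnpGenotypeTable | None = None,
    match_overlap: float = 0.5,
    min_informative: int = 2,
) -> list[CnvCall]:
    """Classify every proband call; upgrade duo deletions where possible."""
    for call in calls:
        if not pedigree.is_proband(call.sample):
            continue
        label = classify_inheritance(call, pedigree, calls, match_overlap)
        if label == "unknown" and call.type == "del" and genotypes is not None:
            mother, father = pedigree.parents_of(call.sample)
            parent = mother or father
            if parent is not None and (mother is None or father is None):
                verdict = infer_denovo_deletion(
                    call, parent, genotypes, min_informative
                )
                if verdict == "de_novo_inferred":
                    label = "de_novo_inferred"
        call.inheritance = label
    return calls
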