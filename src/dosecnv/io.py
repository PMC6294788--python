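"""Readers and writers for the pipeline's plain-text interchange formats.

Intervals are BED-style: 0-based, half-open. Matrices are TSV with the
feature id in the first column and sample ids as the header. Lines
beginning with '#' are comments; every writer emits a tool/seed header.
The calls report additionally prints 1-based inclusive positions, the
convention of clinical CNV tables.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .caller import CnvCall, validate_probe_map

_COMMENT = "#"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment=_COMMENT, **kwargs)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment=_COMMENT, header=None,
        names=["chrom", "start", "end", "probe_id"],
        dtype={"chrom": str},
    )
    return validate_probe_map(df)


def read_gene_models(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment=_COMMENT, header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str},
    )


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample matrix; first column is the feature id."""
    return _read_tsv(path, index_col=0)


def read_totals(path) -> pd.Series:
    df = _read_tsv(path, index_col=0)
    return df.iloc[:, 0]


def read_pedigree_table(path) -> pd.DataFrame:
    return _read_tsv(path, dtype=str).fillna("")


def read_common_db_frame(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment=_COMMENT, header=None,
        names=["chrom", "start", "end", "maf", "study_n"],
        dtype={"chrom": str},
    )


def read_genotype_table(path) -> pd.DataFrame:
    return _read_tsv(path, dtype={"sample": str, "chrom": str, "alleles": str})


CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "pos_1based", "type",
    "n_probes", "mean_score", "inheritance", "filter_status",
]


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    rows = [
        (
            c.sample, c.chrom, c.start, c.end,
            f"{c.chrom}:{c.start + 1}-{c.end}",
            c.type, c.n_probes, round(c.mean_score, 6), c.inheritance,
            c.filter_status,
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls_tsv(calls: list[CnvCall], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path) -> list[CnvCall]:
    df = _read_tsv(path, dtype={"sample": str, "chrom": str})
    calls = []
    for r in df.itertuples():
        calls.append(
            CnvCall(
                sample=str(r.sample), chrom=str(r.chrom),
                start=int(r.start), end=int(r.end), type=str(r.type),
                n_probes=int(r.n_probes), mean_score=float(r.mean_score),
                inheritance=str(r.inheritance),
                filter_status=str(r.filter_status),
            )
        )
    return calls


def write_calls_bed(calls: list[CnvCall], path, header: str = "") -> None:
    """BED5: name is the call type, score is mean SVD-ZRPKM x 100, rounded."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for c in calls:
            score = int(round(100 * c.mean_score))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.type}\t{score}\n")


def write_matrix(df: pd.DataFrame, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", float_format="%.17g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
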