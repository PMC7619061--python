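"""Readers and writers for the pipeline's tabular formats.

Formats: survival CSV (``animal_id,time_weeks,event``), SFS TSV
(``n<TAB>count``), VAF TSV, variant TSV, wide cohort-pileup TSV, BED
(0-based half-open; converted at this boundary, see varfilter), VCF (via
pysam; AD/DP read, FILTER reason codes written), and JSON result bundles.
Malformed records raise :class:`FileFormatError` naming the line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FileFormatError",
    "read_survival_csv",
    "write_survival_csv",
    "read_sfs_tsv",
    "write_sfs_tsv",
    "read_vaf_tsv",
    "write_vaf_tsv",
    "read_bed",
    "write_bed",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "read_vcf",
    "write_vcf",
    "read_json",
    "write_json",
]


class FileFormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_table(path, sep: str, columns: dict[str, type], header: bool = True):
    """Line-validating delimited reader with 1-based line numbers on error."""
    rows = []
    names = list(columns)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FileFormatError(f"{path}: empty file")
    start = 0
    if header:
        got = lines[0].split(sep)
        if got != names:
            raise FileFormatError(
                f"{path}: line 1: expected header {names}, got {got}"
            )
        start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != len(names):
            raise FileFormatError(
                f"{path}: line {ln}: expected {len(names)} fields, got {len(fields)}"
            )
        row = []
        for value, (name, typ) in zip(fields, columns.items()):
            try:
                row.append(typ(value))
            except ValueError as exc:
                raise FileFormatError(
                    f"{path}: line {ln}: field {name!r}: {exc}"
                ) from None
        rows.append(row)
    return pd.DataFrame(rows, columns=names)


def read_survival_csv(path) -> pd.DataFrame:
    df = _parse_table(
        path, ",", {"animal_id": str, "time_weeks": float, "event": int}
    )
    if not df["event"].isin([0, 1]).all():
        raise FileFormatError(f"{path}: event flags must be 0 or 1")
    if (df["time_weeks"] < 0).any():
        raise FileFormatError(f"{path}: negative times")
    return df


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df[["animal_id", "time_weeks", "event"]].to_csv(path, index=False)


def read_sfs_tsv(path) -> dict[int, int]:
    df = _parse_table(path, "\t", {"n": int, "count": int})
    return dict(zip(df["n"], df["count"]))


def write_sfs_tsv(counts: dict[int, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("n\tcount\n")
        for n in sorted(counts):
            fh.write(f"{n}\t{counts[n]}\n")


_VAF_COLS = {
    "chrom": str,
    "pos": int,
    "true_vaf": float,
    "observed_vaf": float,
    "depth": int,
    "variant_reads": int,
}


def read_vaf_tsv(path) -> pd.DataFrame:
    return _parse_table(path, "\t", _VAF_COLS)


def write_vaf_tsv(df: pd.DataFrame, path) -> None:
    df[list(_VAF_COLS)].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open), no header."""
    df = _parse_table(
        path, "\t", {"chrom": str, "start": int, "end": int}, header=False
    )
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FileFormatError(
            f"{path}: line {bad[0] + 1}: start must be < end"
        )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    """Wide pileup matrix: first column the variant key, then one VAF column
    per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FileFormatError(f"{path}: missing VAF entries")
    return df


def write_cohort_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_vcf(path) -> pd.DataFrame:
    """VCF import: chrom, pos, ref, alt plus AD-derived read counts.

    Structural validation (column counts, integer positions) reports
    1-based line numbers before pysam parses the records.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    saw_header = False
    for ln, line in enumerate(lines, start=1):
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            saw_header = True
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if not saw_header:
            raise FileFormatError(f"{path}: line {ln}: data before #CHROM header")
        if len(fields) < 8:
            raise FileFormatError(
                f"{path}: line {ln}: VCF record has {len(fields)} fields (< 8)"
            )
        try:
            int(fields[1])
        except ValueError:
            raise FileFormatError(
                f"{path}: line {ln}: POS {fields[1]!r} is not an integer"
            ) from None
    if not saw_header:
        raise FileFormatError(f"{path}: missing #CHROM header line")

    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt_i, alt in enumerate(rec.alts or ()):
                var_reads = ref_reads = None
                if samples:
                    fmt = rec.samples[samples[0]]
                    ad = fmt.get("AD")
                    if ad is not None:
                        ref_reads = ad[0]
                        var_reads = ad[alt_i + 1] if len(ad) > alt_i + 1 else None
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "variant_reads": var_reads,
                        "reference_reads": ref_reads,
                        "filter": ";".join(rec.filter.keys()) or "PASS",
                    }
                )
    return pd.DataFrame(rows)


def write_vcf(df: pd.DataFrame, path, sample_id: str = "SAMPLE") -> None:
    """Write variants (chrom,pos,ref,alt,variant_reads,reference_reads and an
    optional ``reason`` column) as a single-sample VCF with FILTER codes."""
    import pysam

    header = pysam.VariantHeader()
    reasons = set()
    if "reason" in df.columns:
        reasons = {str(r).split(":")[0].replace("<", "lt").replace(" ", "_")
                   for r in df["reason"].dropna()}
    for code in sorted(reasons):
        header.filters.add(code, None, None, "removed by clonedrift filter")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.formats.add("DP", "1", "Integer", "Read depth")
    for chrom in pd.unique(df["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in df.sort_values(["chrom", "pos"]).iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            if "reason" in df.columns and pd.notna(row.get("reason")):
                code = str(row["reason"]).split(":")[0].replace("<", "lt").replace(" ", "_")
                rec.filter.add(code)
            else:
                rec.filter.add("PASS")
            vr = int(row["variant_reads"])
            rr = int(row["reference_reads"])
            rec.samples[sample_id]["AD"] = (rr, vr)
            rec.samples[sample_id]["DP"] = rr + vr
            out.write(rec)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        return super().default(obj)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
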