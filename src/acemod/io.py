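"""Readers and writers for every format the pipeline touches.

TSV dialect: tab-separated, UTF-8, mandatory header row, "NA" for missing.
Scientific notation is normalized on read: both plain "3.306e-291" and the
typeset "3.306 × 10^−291" dialect (Unicode multiplication sign and minus)
are accepted; everything is emitted as plain e-notation.  VCF is v4.2 with
GT-only genotype fields, read through cyvcf2.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import HET, HOM, MISSING, REF, GenotypeMatrix
from .phenotyping import ACEPhenotype, PhenotypeRecord
from .pqtl_screen import SummaryStatRecord

logger = logging.getLogger(__name__)

NA = "NA"


class ParseError(ValueError):
    """Malformed input file."""


# -- number dialects -------------------------------------------------------

_TYPESET_RE = re.compile(
    r"^\s*(?P<mantissa>[^\s×x*]+)\s*[×x*]\s*10\s*\^?\s*(?P<exponent>[−\-+]?\d+)\s*$"
)


def parse_scientific(text: str | float) -> float:
    """Parse a number in plain or typeset scientific notation.

    Handles "1.5e-7", "3.306 × 10^−291" (Unicode minus/multiplication sign),
    "3 x 10^-7", and superscript exponents pasted from typeset tables.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    s = s.replace("−", "-").replace("–", "-")
    # superscript digits and signs occasionally survive copy/paste
    s = s.translate(str.maketrans("⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺", "0123456789-+"))
    m = _TYPESET_RE.match(s)
    if m:
        s = f"{m.group('mantissa')}e{m.group('exponent')}"
    try:
        return float(s)
    except ValueError as exc:
        raise ParseError(f"cannot parse number: {text!r}") from exc


def format_scientific(x: float) -> str:
    """Plain e-notation with enough digits to round-trip."""
    return repr(float(x))


# -- summary statistics ----------------------------------------------------

SUMMARY_COLUMNS = ("variant_id", "gene", "consequence", "beta", "p_value", "maf")


def read_summary_stats(path: str | Path) -> list[SummaryStatRecord]:
    """Read a summary-statistic TSV; extra columns become annotations."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in SUMMARY_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            SummaryStatRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                consequence=row["consequence"],
                beta=parse_scientific(row["beta"]),
                p_value=parse_scientific(row["p_value"]),
                maf=parse_scientific(row["maf"]),
                annotations={
                    c: row[c] for c in extra if isinstance(row[c], str) and row[c]
                },
            )
        )
    return records


def write_summary_stats(records: Sequence[SummaryStatRecord], path: str | Path) -> None:
    rows = [
        {
            "variant_id": r.variant_id,
            "gene": r.gene,
            "consequence": r.consequence,
            "beta": format_scientific(r.beta),
            "p_value": format_scientific(r.p_value),
            "maf": format_scientific(r.maf),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS)).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


# -- phenotype tables ------------------------------------------------------

PHENOTYPE_COLUMNS = (
    "sample_id",
    "id_genotype",
    "y215c_copies",
    "assay_9b9",
    "assay_1g12",
    "assay_5b3",
)


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PhenotypeRecord(
                sample_id=row["sample_id"],
                id_genotype=row["id_genotype"] if isinstance(row["id_genotype"], str) and row["id_genotype"] else "unknown",
                y215c_copies=int(row["y215c_copies"]),
                assay_9b9=_opt_float(row["assay_9b9"]),
                assay_1g12=_opt_float(row["assay_1g12"]),
                assay_5b3=_opt_float(row["assay_5b3"]),
            )
        )
    return records


def _opt_float(value: str | float) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", NA):
        return None
    return parse_scientific(value)


def write_phenotype_table(records: Sequence[PhenotypeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "id_genotype": r.id_genotype,
                "y215c_copies": r.y215c_copies,
                "assay_9b9": NA if r.assay_9b9 is None else format_scientific(r.assay_9b9),
                "assay_1g12": NA if r.assay_1g12 is None else format_scientific(r.assay_1g12),
                "assay_5b3": NA if r.assay_5b3 is None else format_scientific(r.assay_5b3),
            }
        )
    pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_phenotype_report(phenotypes: Sequence[ACEPhenotype], path: str | Path) -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "percent": format_scientific(p.percent_of_control),
            "corrected_percent": format_scientific(p.corrected_percent),
            "bin": p.bin,
            "binding_ratio": NA
            if p.binding_ratio_percent is None
            else format_scientific(p.binding_ratio_percent),
            "mutant_marker_positive": str(p.mutant_marker_positive).lower(),
            "genotype_corrected": str(p.genotype_corrected).lower(),
        }
        for p in phenotypes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_report(path: str | Path) -> dict[str, dict]:
    """Phenotype report keyed by sample id (corrected percent + bin)."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    out = {}
    for _, row in df.iterrows():
        out[row["sample_id"]] = {
            "percent": parse_scientific(row["percent"]),
            "corrected_percent": parse_scientific(row["corrected_percent"]),
            "bin": row["bin"],
        }
    return out


# -- genotype matrices -----------------------------------------------------

_DOSAGE_TO_CALL = {"0": REF, "1": HET, "2": HOM, NA: MISSING}
_CALL_TO_DOSAGE = {REF: "0", HET: "1", HOM: "2", MISSING: NA}


def read_variant_calls(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a VCF (``.vcf``) or a sample x variant dosage TSV.

    TSV layout: first column ``sample_id``, one column per variant holding
    {0,1,2,NA}.  Multi-allelic VCF records are collapsed to carrier states
    with a logged count.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path)
    return _read_dosage_tsv(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicated sample ids in VCF header")
    if not samples:
        raise ParseError(f"{path}: VCF has no sample columns")

    variant_ids: list[str] = []
    gene_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
    gt_map = {0: REF, 1: HET, 2: MISSING, 3: HOM}
    for v in vcf:
        if len(v.ALT) > 1:
            n_multiallelic += 1
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{','.join(v.ALT)}"
        if vid in gene_of or vid in variant_ids:
            raise ParseError(f"{path}: duplicate variant id {vid}")
        gene = v.INFO.get("GENE")
        if gene:
            gene_of[vid] = str(gene)
        variant_ids.append(vid)
        columns.append(
            np.array([gt_map[int(t)] for t in v.gt_types], dtype=np.int8)
        )
    vcf.close()
    if n_multiallelic:
        logger.info("collapsed %d multi-allelic records to carrier states", n_multiallelic)
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples, variant_ids=variant_ids, calls=calls, gene_of=gene_of
    )


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[], keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    samples = df["sample_id"].tolist()
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicated sample ids")
    variant_ids = list(df.columns[1:])
    calls = np.empty((len(samples), len(variant_ids)), dtype=np.int8)
    for j, vid in enumerate(variant_ids):
        for i, cell in enumerate(df[vid]):
            cell = str(cell).strip()
            if cell not in _DOSAGE_TO_CALL:
                raise ParseError(
                    f"{path}: line {i + 2}: invalid dosage {cell!r} for {vid}"
                )
            calls[i, j] = _DOSAGE_TO_CALL[cell]
    return GenotypeMatrix(sample_ids=samples, variant_ids=variant_ids, calls=calls)


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    data = {"sample_id": matrix.sample_ids}
    for j, vid in enumerate(matrix.variant_ids):
        data[vid] = [_CALL_TO_DOSAGE[int(c)] for c in matrix.calls[:, j]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


_GT_STRINGS = {REF: "0/0", HET: "0/1", HOM: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF v4.2 with GT-only genotypes.

    Positions are synthetic (variants are keyed by ID, no genome build is
    assumed); genes travel in ``INFO/GENE``.  Write -> read round-trips the
    matrix exactly apart from the group map, which travels separately.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.sample_ids),
    ]
    for j, vid in enumerate(matrix.variant_ids):
        gene = matrix.gene_of.get(vid)
        info = f"GENE={gene}" if gene else "."
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[:, j])
        lines.append(f"1\t{j + 1}\t{vid}\tA\tG\t.\t.\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_group_table(path: str | Path) -> dict[str, str]:
    """TSV with columns sample_id, group ('high'/'low')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ParseError(f"{path}: expected columns sample_id, group")
    bad = sorted(set(df["group"]) - {"high", "low"})
    if bad:
        raise ParseError(f"{path}: invalid group labels {bad}")
    return dict(zip(df["sample_id"], df["group"]))


def write_group_table(group: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(group.keys()), "group": list(group.values())}
    ).to_csv(path, sep="\t", index=False)


# -- packaged fixtures -----------------------------------------------------


def _data_path(name: str):
    return resources.files("acemod.data").joinpath(name)


def load_pqtl_shortlist() -> list[SummaryStatRecord]:
    """The 17-row exome-wide significant pQTL table shipped with the package.

    MAF is stored per 100,000 in the fixture and converted to a fraction.
    """
    with resources.as_file(_data_path("pqtl_shortlist.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        records.append(
            SummaryStatRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                consequence=row["consequence"],
                beta=parse_scientific(row["beta"]),
                p_value=parse_scientific(row["p_value"]),
                maf=parse_scientific(row["maf_per_100k"]) / 100_000.0,
            )
        )
    return records


def load_population_frequency_table() -> pd.DataFrame:
    """Cohort carrier-count table: n_subjects, printed per-100k rate,
    n_carriers, and a flag for rows that reproduce under the package's
    rounding convention."""
    with resources.as_file(_data_path("population_frequency.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["reproducible"] = df["reproducible"] == "yes"
    return df


def load_exclusive_variant_grid() -> GenotypeMatrix:
    """The recurrence-grid fixture: 42 exclusive variants x 15 elevated-level
    carriers, cells in {Het, Hom, -}.  All samples are grouped "high"; the
    per-100k frequency columns are pass-through annotations and dropped.
    """
    with resources.as_file(_data_path("exclusive_variant_grid.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    meta = {"variant_id", "gene", "cdna", "gnomad_per_100k", "fmba_per_100k"}
    sample_ids = [c for c in df.columns if c not in meta]
    cell_map = {"-": REF, "Het": HET, "Hom": HOM}
    calls = np.zeros((len(sample_ids), len(df)), dtype=np.int8)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, s in enumerate(sample_ids):
            calls[i, j] = cell_map[row[s]]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_ids=df["variant_id"].tolist(),
        calls=calls,
        group={s: "high" for s in sample_ids},
        gene_of=dict(zip(df["variant_id"], df["gene"])),
    )
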