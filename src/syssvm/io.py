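"""Readers and writers for the tabular formats the pipeline consumes.

All tables are TSV with headers; gene sets use the GMT dialect (name,
description, members; trailing tabs tolerated). BED-like coordinates are
0-based half-open. Boolean predictor calls are serialized as 0/1 with an
empty field or the configured sentinel for missing call groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alterations import (
    Consequence,
    CopyNumberSegment,
    GeneInterval,
    SmallVariant,
    StructuralVariant,
    SVType,
)
from .germline import GermlineVariant
from .pathways import GeneSetCollection

logger = logging.getLogger(__name__)

NA = "NA"

FUNCTIONAL_PREDICTOR_COLUMNS = [
    "SIFT", "PolyPhen2_HDIV", "PolyPhen2_HVAR", "MutationTaster",
    "MutationAssessor", "LRT", "FATHMM",
]
CONSERVATION_PREDICTOR_COLUMNS = ["PhyloP", "GERP_RS", "SiPhy"]
SPLICING_PREDICTOR_COLUMNS = ["dbscSNV_ada", "dbscSNV_rf"]


class TableFormatError(ValueError):
    """A table row failed validation; the message carries the line number."""


def _read_tsv(path: str | Path, required: Sequence[str], na: str = NA) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    return frame.replace({na: None, "": None})


def _parse(path, row_number, value, caster, column):
    try:
        return caster(value)
    except (TypeError, ValueError) as exc:
        raise TableFormatError(
            f"{path}: line {row_number}: bad value {value!r} in column {column!r}: {exc}"
        ) from exc


def _calls(row, columns) -> tuple[bool, ...] | None:
    vals = [row[c] for c in columns]
    if all(v is None for v in vals):
        return None
    if any(v is None for v in vals):
        raise ValueError(f"partially missing predictor calls in {columns}")
    return tuple(v in ("1", "True", "true") for v in vals)


def _fmt_calls(calls: tuple[bool, ...] | None, n: int, na: str) -> list[str]:
    if calls is None:
        return [na] * n
    return [str(int(c)) for c in calls]


VARIANT_COLUMNS = (
    ["sample", "gene", "consequence"]
    + FUNCTIONAL_PREDICTOR_COLUMNS
    + CONSERVATION_PREDICTOR_COLUMNS
    + SPLICING_PREDICTOR_COLUMNS
    + ["vaf", "indel_len", "gof"]
)


def read_variants(path: str | Path, na: str = NA) -> list[SmallVariant]:
    frame = _read_tsv(path, VARIANT_COLUMNS, na=na)
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        out.append(
            SmallVariant(
                sample_id=row["sample"],
                gene_id=row["gene"],
                consequence=_parse(path, i, row["consequence"], Consequence, "consequence"),
                vaf=_parse(path, i, row["vaf"], float, "vaf"),
                indel_length=_parse(path, i, row["indel_len"], int, "indel_len"),
                functional_calls=_parse(
                    path, i, row, lambda r: _calls(r, FUNCTIONAL_PREDICTOR_COLUMNS), "functional"
                ),
                conservation_calls=_parse(
                    path, i, row, lambda r: _calls(r, CONSERVATION_PREDICTOR_COLUMNS), "conservation"
                ),
                splicing_calls=_parse(
                    path, i, row, lambda r: _calls(r, SPLICING_PREDICTOR_COLUMNS), "splicing"
                ),
                gof_flag=row["gof"] in ("1", "True", "true"),
            )
        )
    return out


def write_variants(variants: Sequence[SmallVariant], path: str | Path, na: str = NA) -> None:
    rows = []
    for v in variants:
        rows.append(
            [v.sample_id, v.gene_id, v.consequence.value]
            + _fmt_calls(v.functional_calls, 7, na)
            + _fmt_calls(v.conservation_calls, 3, na)
            + _fmt_calls(v.splicing_calls, 2, na)
            + [repr(v.vaf), str(v.indel_length), str(int(v.gof_flag))]
        )
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "segment_mean", "cn", "ploidy"]


def read_segments(path: str | Path, na: str = NA) -> list[CopyNumberSegment]:
    frame = _read_tsv(path, SEGMENT_COLUMNS, na=na)
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        out.append(
            CopyNumberSegment(
                sample_id=row["sample"],
                chrom=row["chrom"],
                start=_parse(path, i, row["start"], int, "start"),
                end=_parse(path, i, row["end"], int, "end"),
                segment_mean=(
                    None if row["segment_mean"] is None
                    else _parse(path, i, row["segment_mean"], float, "segment_mean")
                ),
                absolute_cn=(
                    None if row["cn"] is None else _parse(path, i, row["cn"], float, "cn")
                ),
                sample_ploidy=_parse(path, i, row["ploidy"], float, "ploidy"),
            )
        )
    return out


def write_segments(segments: Sequence[CopyNumberSegment], path: str | Path, na: str = NA) -> None:
    rows = [
        [
            s.sample_id, s.chrom, str(s.start), str(s.end),
            na if s.segment_mean is None else repr(s.segment_mean),
            na if s.absolute_cn is None else repr(s.absolute_cn),
            repr(s.sample_ploidy),
        ]
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_svs(path: str | Path) -> list[StructuralVariant]:
    frame = _read_tsv(path, ["sample", "gene", "sv_type"])
    return [
        StructuralVariant(
            row["sample"], row["gene"], _parse(path, i, row["sv_type"], SVType, "sv_type")
        )
        for i, row in enumerate(frame.to_dict("records"), start=2)
    ]


def write_svs(svs: Sequence[StructuralVariant], path: str | Path) -> None:
    pd.DataFrame(
        [[s.sample_id, s.gene_id, s.sv_type.value] for s in svs],
        columns=["sample", "gene", "sv_type"],
    ).to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    frame = _read_tsv(path, ["gene", "chrom", "start", "end"])
    return [
        GeneInterval(
            row["gene"], row["chrom"],
            _parse(path, i, row["start"], int, "start"),
            _parse(path, i, row["end"], int, "end"),
        )
        for i, row in enumerate(frame.to_dict("records"), start=2)
    ]


def write_gene_intervals(intervals: Sequence[GeneInterval], path: str | Path) -> None:
    pd.DataFrame(
        [[g.gene_id, g.chrom, str(g.start), str(g.end)] for g in intervals],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_properties(path: str | Path, na: str = NA) -> pd.DataFrame:
    """Systems-level property table indexed by gene, NaN for missing values."""
    frame = pd.read_csv(
        path, sep="\t", na_values=[na], keep_default_na=False,
        float_precision="round_trip",
    )
    if "gene_id" not in frame.columns:
        raise TableFormatError(f"{path}: missing column 'gene_id'")
    frame = frame.set_index("gene_id")
    bool_map = {"True": True, "False": False, "0": False, "1": True}
    for col in frame.columns:
        if frame[col].dtype == object:
            observed = frame[col].dropna()
            if set(observed.astype(str).unique()) <= set(bool_map):
                frame[col] = frame[col].map(
                    lambda v: v if isinstance(v, bool) else bool_map[str(v)],
                    na_action="ignore",
                )
    return frame


def write_properties(props: pd.DataFrame, path: str | Path, na: str = NA) -> None:
    props.rename_axis("gene_id").to_csv(path, sep="\t", na_rep=na)


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """GMT reader: name <tab> description <tab> members...; trailing tabs ignored."""
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\t\n").split("\t")
        if len(parts) < 3:
            raise TableFormatError(f"{path}: line {lineno}: GMT rows need >=3 fields")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise TableFormatError(f"{path}: line {lineno}: empty gene set {name!r}")
        sets[name] = frozenset(genes)
    return GeneSetCollection(sets=sets)


def write_gmt(c: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description] + sorted(c.sets[name])) for name in sorted(c.sets)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pathway_levels(path: str | Path) -> dict[str, int]:
    frame = _read_tsv(path, ["pathway", "level"])
    return {
        row["pathway"]: _parse(path, i, row["level"], int, "level")
        for i, row in enumerate(frame.to_dict("records"), start=2)
    }


def write_pathway_levels(levels: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(levels.items()), columns=["pathway", "level"]
    ).to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.Series:
    frame = _read_tsv(path, ["gene_id", "expression"])
    return pd.Series(
        [float(v) for v in frame["expression"]],
        index=pd.Index(frame["gene_id"], name="gene_id"),
        name="expression",
    )


def write_expression(expression: pd.Series, path: str | Path) -> None:
    expression.rename("expression").rename_axis("gene_id").to_csv(path, sep="\t")


GERMLINE_COLUMNS = (
    ["sample", "gene", "genotype", "vaf", "depth", "consequence"]
    + FUNCTIONAL_PREDICTOR_COLUMNS
    + ["maf_cohort", "maf_exac", "maf_1kg", "site_id"]
)


def read_germline(path: str | Path, na: str = NA) -> list[GermlineVariant]:
    frame = _read_tsv(path, GERMLINE_COLUMNS, na=na)
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        out.append(
            GermlineVariant(
                sample_id=row["sample"],
                gene_id=row["gene"],
                genotype=row["genotype"],
                vaf=_parse(path, i, row["vaf"], float, "vaf"),
                depth=_parse(path, i, row["depth"], int, "depth"),
                consequence=_parse(path, i, row["consequence"], Consequence, "consequence"),
                functional_calls=_parse(
                    path, i, row, lambda r: _calls(r, FUNCTIONAL_PREDICTOR_COLUMNS), "functional"
                ),
                maf_cohort=_parse(path, i, row["maf_cohort"], float, "maf_cohort"),
                maf_exac=_parse(path, i, row["maf_exac"], float, "maf_exac"),
                maf_1kg=_parse(path, i, row["maf_1kg"], float, "maf_1kg"),
                site_id=row["site_id"],
            )
        )
    return out


def write_germline(variants: Sequence[GermlineVariant], path: str | Path, na: str = NA) -> None:
    rows = []
    for v in variants:
        rows.append(
            [v.sample_id, v.gene_id, v.genotype, repr(v.vaf), str(v.depth),
             v.consequence.value]
            + _fmt_calls(v.functional_calls, 7, na)
            + [repr(v.maf_cohort), repr(v.maf_exac), repr(v.maf_1kg),
               v.site_id or na]
        )
    pd.DataFrame(rows, columns=GERMLINE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(["sample_id", "gene_id"])


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.reset_index().to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path, info_keys: dict[str, str]) -> list[SmallVariant]:
    """Minimal VCF ingestion for small variants.

    ``info_keys`` names the INFO fields holding sample, gene, consequence,
    the comma-separated predictor call groups, VAF, indel length and the
    gain-of-function flag, e.g. ``{"gene": "GENE", "consequence": "CSQ",
    "functional": "FUNC", "conservation": "CONS", "splicing": "SPLICE",
    "vaf": "VAF", "sample": "SAMPLE", "gof": "GOF"}``.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise TableFormatError(f"{path}: line {lineno}: not a VCF data row")
        ref, alt = fields[3], fields[4]
        info = dict(
            kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv
        )
        flags = {kv for kv in fields[7].split(";") if "=" not in kv}

        def calls(key: str) -> tuple[bool, ...] | None:
            raw = info.get(info_keys.get(key, ""), None)
            if raw is None:
                return None
            return tuple(tok == "1" for tok in raw.split(","))

        indel = abs(len(alt) - len(ref))
        out.append(
            SmallVariant(
                sample_id=info[info_keys["sample"]],
                gene_id=info[info_keys["gene"]],
                consequence=Consequence(info[info_keys["consequence"]]),
                vaf=float(info[info_keys["vaf"]]),
                indel_length=indel,
                functional_calls=calls("functional"),
                conservation_calls=calls("conservation"),
                splicing_calls=calls("splicing"),
                gof_flag=info_keys.get("gof", "") in flags
                or info.get(info_keys.get("gof", ""), "0") == "1",
            )
        )
    return out


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of a CLI stage sufficient to re-execute it bit-identically."""

    command: str
    version: str
    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: list[str] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)  # name, seconds, n_records

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        if p.exists() and p.is_file():
            self.inputs[str(p)] = sha256(p)

    def add_stage(self, name: str, seconds: float, n_records: int) -> None:
        self.stages.append(
            {"name": name, "seconds": round(seconds, 3), "n_records": n_records}
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
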