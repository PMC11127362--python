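"""File formats: GFF3 gene catalogs, TSV tables, JSON truth/model dumps.

Conventions: coordinates are 1-based inclusive (GFF3); missing values
in TSV tables are '.'; non-detect qPCR CT values are the sentinel "ND".
Catalog attributes carried in GFF3 column 9: ID, signature, CAZy, EC,
EC_name, taxon (list-valued attributes comma-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cgc import CATALOG_COLUMNS, SIGNATURES
from .synthetic import TruthTable

MISSING = "."
NONDETECT = "ND"


def _fmt_attr(value: str) -> str:
    return value if value else MISSING


def write_catalog_gff3(catalog: pd.DataFrame, path) -> None:
    """Write a gene catalog as GFF3 with annotation attributes."""
    lines = ["##gff-version 3"]
    for _, r in catalog.iterrows():
        attrs = ";".join(
            [
                f"ID={r['gene_id']}",
                f"signature={r['signature']}",
                f"CAZy={_fmt_attr(r['cazy_families'])}",
                f"EC={_fmt_attr(r['ec_numbers'])}",
                f"EC_name={_fmt_attr(r['ec_names'])}",
                f"taxon={_fmt_attr(r['taxon'])}",
            ]
        )
        lines.append(
            "\t".join(
                [
                    str(r["contig_id"]),
                    "prebioresponse",
                    "gene",
                    str(int(r["start_bp"])),
                    str(int(r["end_bp"])),
                    ".",
                    r["strand"],
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog_gff3(path) -> pd.DataFrame:
    """Parse and validate a GFF3 gene catalog.

    Errors carry 1-based line numbers.  The catalog is returned sorted
    by (contig, start) with ``order_index`` derived, and round-trips
    losslessly through :func:`write_catalog_gff3`.
    """
    rows = []
    seen_ids: dict[str, int] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
        contig, _source, _type, start, end, _score, strand, _phase, attrs = fields
        try:
            start_bp, end_bp = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinates") from exc
        if start_bp < 1 or end_bp < start_bp:
            raise ValueError(
                f"line {lineno}: invalid coordinates {start_bp}..{end_bp}"
            )
        if strand not in ("+", "-"):
            raise ValueError(f"line {lineno}: invalid strand {strand!r}")
        attr_map = {}
        for chunk in attrs.split(";"):
            if "=" not in chunk:
                raise ValueError(f"line {lineno}: malformed attribute {chunk!r}")
            key, value = chunk.split("=", 1)
            attr_map[key] = value
        if "ID" not in attr_map:
            raise ValueError(f"line {lineno}: missing ID attribute")
        gid = attr_map["ID"]
        if gid in seen_ids:
            raise ValueError(
                f"line {lineno}: duplicate gene id {gid!r} (first at line {seen_ids[gid]})"
            )
        seen_ids[gid] = lineno
        signature = attr_map.get("signature", "NONE")
        if signature not in SIGNATURES:
            raise ValueError(f"line {lineno}: unknown signature {signature!r}")

        def attr(key: str) -> str:
            v = attr_map.get(key, MISSING)
            return "" if v == MISSING else v

        rows.append(
            {
                "gene_id": gid,
                "contig_id": contig,
                "start_bp": start_bp,
                "end_bp": end_bp,
                "strand": strand,
                "signature": signature,
                "cazy_families": attr("CAZy"),
                "ec_numbers": attr("EC"),
                "ec_names": attr("EC_name"),
                "taxon": attr("taxon"),
            }
        )
    catalog = pd.DataFrame(rows)
    if catalog.empty:
        return pd.DataFrame(columns=CATALOG_COLUMNS)
    catalog = catalog.sort_values(["contig_id", "start_bp"], kind="mergesort")
    catalog["order_index"] = catalog.groupby("contig_id").cumcount()
    for contig, grp in catalog.groupby("contig_id"):
        starts = grp["start_bp"].to_numpy()
        ends = grp["end_bp"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError(f"overlapping gene coordinates on contig {contig}")
    return catalog[CATALOG_COLUMNS].reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a TSV table with '.' for missing values."""
    df.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING], index_col=index_col)


def write_qpcr_wells(wells: pd.DataFrame, path) -> None:
    """Well-level CT table; non-detect wells carry the "ND" sentinel."""
    out = wells.copy()
    out["ct"] = out["ct"].map(lambda v: NONDETECT if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def read_qpcr_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ct": str})
    df["ct"] = df["ct"].map(lambda v: np.nan if v == NONDETECT else float(v))
    return df


def write_truth(truth: TruthTable, path) -> None:
    payload = {
        "phenotype": {
            s: truth.phenotype.loc[s].to_dict() for s in truth.phenotype.index
        },
        "planted_genes": truth.planted_genes,
        "planted_cgcs": truth.planted_cgcs,
        "decoy_genes": truth.decoy_genes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> TruthTable:
    payload = json.loads(Path(path).read_text())
    phen = pd.DataFrame.from_dict(payload["phenotype"], orient="index")
    phen = phen.sort_index()
    return TruthTable(
        phenotype=phen,
        planted_genes=payload["planted_genes"],
        planted_cgcs=payload["planted_cgcs"],
        decoy_genes=payload["decoy_genes"],
    )
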