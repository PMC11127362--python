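"""Carbohydrate gene cluster (CGC) detection and substrate-specific filtering.

A CGC is a contig-local run of signature genes (CAZyme, transporter TC,
transcription factor TF) in which consecutive signature genes are
separated by at most ``max_gap`` non-signature genes, containing at
least one CAZyme and at least one transporter.  TF genes count as
signature (they do not break runs) but do not satisfy the transporter
requirement.  Gaps are counted in genes, not base pairs, and clusters
never cross contig boundaries.

Substrate specificity is imposed downstream by a CAZy-family whitelist
followed by an enzyme-name (EC) blacklist that removes families whose
common members are irrelevant to the substrate (e.g. GH1/GH2/GH3
beta-glucosidases under a xylooligosaccharide specification).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATALOG_COLUMNS = [
    "gene_id",
    "contig_id",
    "order_index",
    "start_bp",
    "end_bp",
    "strand",
    "signature",
    "cazy_families",
    "ec_numbers",
    "ec_names",
    "taxon",
]

SIGNATURES = ("CAZYME", "TC", "TF", "NONE")

#: enzyme names removed from substrate-specific gene lists, with their
#: EC numbers; a gene matches on either the name or the EC number
EC_NAME_BLACKLIST: dict[str, str] = {
    "beta-glucosidase": "3.2.1.21",
    "beta-galactosidase": "3.2.1.23",
    "beta-mannosidase": "3.2.1.25",
    "beta-N-acetylhexosaminidase": "3.2.1.52",
    "arabinan endo-1,5-alpha-L-arabinosidase": "3.2.1.99",
}

#: default CAZy-family whitelists per substrate (configurable; the
#: GH1/GH2/GH3 false positives under XOS are handled by the blacklist)
DEFAULT_WHITELISTS: dict[str, frozenset[str]] = {
    "FOS": frozenset({"GH32", "GH68"}),
    "INU": frozenset({"GH32", "GH68", "GH91"}),
    "XOS": frozenset(
        {"GH8", "GH10", "GH43", "GH120", "GH1", "GH2", "GH3", "GH30",
         "GH51", "GH67", "GH115"}
    ),
}

SUBSTRATE_LETTER = {"FOS": "F", "INU": "I", "XOS": "X"}


@dataclass(frozen=True)
class CgcParams:
    """Cluster-calling rule: gap threshold and composition requirements."""

    max_gap: int = 5
    require_tc: bool = True
    require_cazyme: bool = True

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class SubstrateSpec:
    """Substrate-specific gene filter: family whitelist + EC-name blacklist."""

    substrate: str
    family_whitelist: frozenset[str]
    ec_name_blacklist: dict[str, str] = field(
        default_factory=lambda: dict(EC_NAME_BLACKLIST)
    )

    def __post_init__(self) -> None:
        if not self.family_whitelist:
            raise ValueError("family whitelist must be nonempty")

    @classmethod
    def default(cls, substrate: str) -> "SubstrateSpec":
        if substrate not in DEFAULT_WHITELISTS:
            raise ValueError(f"unknown substrate: {substrate!r}")
        return cls(substrate=substrate, family_whitelist=DEFAULT_WHITELISTS[substrate])


def _split(cell) -> list[str]:
    """Split a comma-joined annotation cell into tokens."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    return [t for t in text.split(",") if t] if text else []


def _family_root(family: str) -> str:
    """GH43_12 -> GH43: subfamilies match on their root family."""
    return family.split("_")[0]


def find_cgcs(catalog: pd.DataFrame, params: CgcParams | None = None) -> pd.DataFrame:
    """Detect carbohydrate gene clusters on every contig.

    ``catalog`` must be sorted by (contig, order_index).  Returns one
    row per cluster with the ordered member gene ids (signature genes
    plus the intervening non-signature genes within the span),
    composition counts and the bp span.
    """
    params = params or CgcParams()
    if catalog.empty:
        return pd.DataFrame(
            columns=["cgc_id", "contig_id", "member_gene_ids",
                     "n_cazyme", "n_tc", "n_tf", "start_bp", "end_bp"]
        )
    clusters = []
    for contig, genes in catalog.groupby("contig_id", sort=True):
        order = genes["order_index"].to_numpy()
        if np.any(np.diff(order) <= 0):
            raise ValueError(f"catalog not sorted by order_index on contig {contig}")
        sig_pos = np.flatnonzero(genes["signature"].to_numpy() != "NONE")
        if sig_pos.size == 0:
            continue
        # split signature genes into runs with <= max_gap intervening
        # non-signature genes between consecutive members
        breaks = np.flatnonzero(np.diff(sig_pos) - 1 > params.max_gap)
        run_starts = np.r_[0, breaks + 1]
        run_ends = np.r_[breaks, sig_pos.size - 1]
        for a, b in zip(run_starts, run_ends):
            lo, hi = sig_pos[a], sig_pos[b]
            members = genes.iloc[lo : hi + 1]
            sigs = members["signature"].to_numpy()
            n_caz = int((sigs == "CAZYME").sum())
            n_tc = int((sigs == "TC").sum())
            n_tf = int((sigs == "TF").sum())
            if params.require_cazyme and n_caz < 1:
                continue
            if params.require_tc and n_tc < 1:
                continue
            clusters.append(
                {
                    "contig_id": contig,
                    "member_gene_ids": list(members["gene_id"]),
                    "n_cazyme": n_caz,
                    "n_tc": n_tc,
                    "n_tf": n_tf,
                    "start_bp": int(members["start_bp"].iloc[0]),
                    "end_bp": int(members["end_bp"].iloc[-1]),
                }
            )
    out = pd.DataFrame(clusters)
    if not out.empty:
        out.insert(0, "cgc_id", [f"CGC{i + 1}" for i in range(len(out))])
    else:
        out = pd.DataFrame(
            columns=["cgc_id", "contig_id", "member_gene_ids",
                     "n_cazyme", "n_tc", "n_tf", "start_bp", "end_bp"]
        )
    return out


def substrate_gene_filter(genes: pd.DataFrame, spec: SubstrateSpec) -> pd.DataFrame:
    """Keep genes with a whitelisted CAZy family, then drop blacklisted enzymes.

    Family matching collapses subfamilies (GH43_12 matches GH43); the
    blacklist matches on either enzyme name or EC number.  Input order
    is preserved.
    """
    if genes.empty:
        return genes.copy()
    fam_ok = genes["cazy_families"].map(
        lambda cell: any(_family_root(f) in spec.family_whitelist for f in _split(cell))
    )
    kept = genes[fam_ok]
    bad_names = set(spec.ec_name_blacklist)
    bad_ecs = set(spec.ec_name_blacklist.values())
    black = kept.apply(
        lambda row: bool(set(_split(row["ec_names"])) & bad_names)
        or bool(set(_split(row["ec_numbers"])) & bad_ecs),
        axis=1,
    )
    return kept[~black].copy()


def responder_association_filter(
    da: pd.DataFrame, q_threshold: float = 0.05
) -> list[str]:
    """Retain responder-associated genes: positive log2FC and q below threshold.

    ``da`` is a differential-abundance result indexed by gene id with
    ``log2fc`` and ``q`` columns (responders as the fold-change numerator).
    """
    mask = (da["log2fc"] > 0) & (da["q"] < q_threshold)
    return list(da.index[mask.fillna(False)])


def clusters_for_genes(
    retained_genes, cgcs: pd.DataFrame, substrate: str
) -> tuple[pd.DataFrame, list[str]]:
    """Select whole clusters containing any retained gene; assign ids.

    Every cluster with at least one retained member is selected in its
    entirety and renamed ``<substrate-letter>CGC<n>`` in discovery
    order.  Returns (selected clusters, retained genes found in no
    cluster -- reported as singletons, not an error).
    """
    retained = set(retained_genes)
    letter = SUBSTRATE_LETTER.get(substrate)
    if letter is None:
        raise ValueError(f"unknown substrate: {substrate!r}")
    in_cluster: set[str] = set()
    picked = []
    for _, row in cgcs.iterrows():
        members = set(row["member_gene_ids"])
        if members & retained:
            picked.append(row)
            in_cluster |= members
    selected = pd.DataFrame(picked).reset_index(drop=True)
    if not selected.empty:
        selected["cgc_id"] = [f"{letter}CGC{i + 1}" for i in range(len(selected))]
        selected["substrate"] = substrate
    else:
        selected = pd.DataFrame(columns=list(cgcs.columns) + ["substrate"])
    singletons = sorted(retained - in_cluster)
    return selected, singletons


def cluster_copy_number(copy_numbers: pd.DataFrame, cgc_row) -> pd.Series:
    """Per-sample cluster totals: sum of member-gene copy numbers.

    ``copy_numbers`` is samples x target-genes with non-detects encoded
    as 0 (or NaN, treated as 0).  Member genes never assayed are
    skipped; a cluster with no assayed member is an error.
    """
    members = [g for g in cgc_row["member_gene_ids"] if g in copy_numbers.columns]
    if not members:
        raise ValueError(
            f"cluster {cgc_row.get('cgc_id', '?')} has no assayed member genes"
        )
    return copy_numbers[members].fillna(0.0).sum(axis=1)
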