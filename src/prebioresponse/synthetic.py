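"""Synthetic fermentation cohorts with planted ground truth.

Emulates the data shapes of a stepwise in vitro fecal fermentation
study: 40 donors fermented with each of three prebiotics (FOS, INU,
XOS) plus a no-prebiotic control (NP), sampled every 12 h over 48 h in
duplicate.  The generator plants

* responder/non-responder phenotypes per subject x substrate (with a
  configurable cross-substrate correlation),
* an elevated acetate+butyrate response in responder arms,
* substrate-specific carbohydrate gene clusters in an annotated gene
  catalog, plus decoy CAZymes carrying blacklisted enzyme names,
* negative-binomially overdispersed gene counts with a planted
  responder fold change on cluster genes,
* qPCR copy numbers for target genes: high in responders, mostly
  non-detect in non-responders, with log-linear standard curves.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgc import CATALOG_COLUMNS

SUBSTRATES = ("FOS", "INU", "XOS")
CONTROL = "NP"

_CAZY_EC = {
    # family -> (ec_number, enzyme name) used for planted/relevant genes
    "GH32": ("3.2.1.26", "beta-fructofuranosidase"),
    "GH68": ("2.4.1.10", "levansucrase"),
    "GH91": ("4.2.2.18", "inulin lyase"),
    "GH8": ("3.2.1.8", "endo-1,4-beta-xylanase"),
    "GH10": ("3.2.1.8", "endo-1,4-beta-xylanase"),
    "GH43": ("3.2.1.37", "beta-xylosidase"),
    "GH120": ("3.2.1.37", "beta-xylosidase"),
}

_DECOY_EC = [
    ("GH3", "3.2.1.21", "beta-glucosidase"),
    ("GH2", "3.2.1.23", "beta-galactosidase"),
    ("GH2", "3.2.1.25", "beta-mannosidase"),
    ("GH20", "3.2.1.52", "beta-N-acetylhexosaminidase"),
    ("GH43", "3.2.1.99", "arabinan endo-1,5-alpha-L-arabinosidase"),
]

_BACKGROUND_FAMILIES = [
    "GH13", "GH25", "GH31", "GH36", "GH77", "GT2", "GT4", "CE1", "PL1",
]

_TAXA = [
    "Bifidobacterium adolescentis",
    "Bifidobacterium longum",
    "Bifidobacterium pseudocatenulatum",
    "Bacteroides uniformis",
    "Escherichia coli",
    "Streptococcus pasteurianus",
    "Clostridium butyricum",
]


@dataclass(frozen=True)
class PlantedCgcSpec:
    """Layout of one planted cluster.

    ``layout`` lists signature tokens in gene order: a CAZy family name,
    "TC" (transporter) or "TF"; ``gap`` non-signature genes are inserted
    between consecutive signature genes.
    """

    substrate: str
    layout: tuple[str, ...]
    gap: int = 1

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be >= 0")
        if not self.layout:
            raise ValueError("layout must be nonempty")

    @property
    def span(self) -> int:
        """Total genes occupied on the contig, including gap genes."""
        return len(self.layout) + self.gap * (len(self.layout) - 1)


def _default_planted_specs() -> tuple[PlantedCgcSpec, ...]:
    return (
        PlantedCgcSpec("FOS", ("GH32", "TC", "GH32", "TC"), gap=1),
        PlantedCgcSpec("INU", ("GH32", "GH91", "TC", "TC"), gap=1),
        PlantedCgcSpec("XOS", ("GH43", "TC", "GH120", "GH8"), gap=2),
    )


@dataclass(frozen=True)
class SimParams:
    """Study-design parameters of the synthetic cohort.

    SCFA arm: additive Gaussian model on baseline-subtracted
    concentrations (subject random intercept + treatment effect +
    residual), clipped at 0 mM.  Counts: NB2 with per-sample depth
    factors.  qPCR: log10-normal copies with explicit non-detects and a
    log-linear CT standard curve.
    """

    n_subjects: int = 40
    substrates: tuple[str, ...] = SUBSTRATES
    responder_prevalence: float = 0.6
    phenotype_correlation: float = 0.5
    delta_ab_responder: float = 20.0  # mean responder Delta(acetate+butyrate), mM
    delta_ab_nonresponder: float = 0.0
    subject_sd: float = 3.0  # random-intercept SD, mM
    residual_sd: float = 3.0  # per-observation SD of the a+b sum, mM
    timepoints_h: tuple[int, ...] = (12, 24, 36, 48)
    replicates: int = 2
    # gene catalog
    n_contigs: int = 30
    genes_per_contig: int = 40
    planted_cgc_specs: tuple[PlantedCgcSpec, ...] = field(
        default_factory=_default_planted_specs
    )
    background_cazyme_rate: float = 0.06
    background_tc_rate: float = 0.05
    background_tf_rate: float = 0.02
    n_decoy_targets: int = 6
    # count matrix
    count_depth_range: tuple[float, float] = (0.5, 1.5)
    count_base_mean: float = 50.0
    nb_dispersion: float = 0.2
    planted_log2fc: float = 2.0
    # qPCR
    qpcr_mu_log10_responder: float = 3.0
    qpcr_mu_log10_nonresponder: float = 1.0
    qpcr_sd: float = 0.5
    nonresponder_detect_prob: float = 0.1
    qpcr_slope: float = -3.32
    qpcr_intercept: float = 40.0
    qpcr_ct_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.timepoints_h:
            raise ValueError("timepoints_h must be nonempty")
        for p in (self.responder_prevalence, self.nonresponder_detect_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not -1.0 < self.phenotype_correlation < 1.0:
            raise ValueError("phenotype_correlation must be in (-1, 1)")
        if self.delta_ab_responder < self.delta_ab_nonresponder:
            raise ValueError("delta_ab_responder must be >= delta_ab_nonresponder")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.qpcr_slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        max_span = max((s.span for s in self.planted_cgc_specs), default=0)
        if max_span > self.genes_per_contig:
            raise ValueError("planted cluster spec wider than a contig")


@dataclass
class TruthTable:
    """Planted ground truth for parameter-recovery tests.

    phenotype: subjects x substrates frame of "R"/"NR".
    planted_genes: substrate -> target gene ids inside planted clusters
        (signature members; these are the qPCR-assayed genes).
    planted_cgcs: one descriptor per planted cluster with the full
        ordered member list (including gap genes).
    decoy_genes: assayed genes carrying no phenotype association.
    """

    phenotype: pd.DataFrame
    planted_genes: dict[str, list[str]] = field(default_factory=dict)
    planted_cgcs: list[dict] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)

    def subjects(self) -> list[str]:
        return list(self.phenotype.index)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _draw_phenotypes(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Correlated R/NR draws via an equicorrelated Gaussian copula."""
    from scipy import stats

    k = len(params.substrates)
    rho = params.phenotype_correlation
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=params.n_subjects,
                                method="cholesky")
    resp = stats.norm.cdf(z) < params.responder_prevalence
    return pd.DataFrame(
        np.where(resp, "R", "NR"),
        index=_subject_ids(params.n_subjects),
        columns=list(params.substrates),
    )


def simulate_scfa(params: SimParams) -> tuple[pd.DataFrame, TruthTable]:
    """Generate the SCFA fermentation table and the phenotype truth.

    One record per subject x arm x replicate x timepoint.  The
    acetate+butyrate sum of a responder arm exceeds the subject's NP
    arm by ``delta_ab_responder`` mM in expectation; pH decreases and
    the percentage of fermented carbohydrate increases affinely with
    the a+b sum, plus noise.  Concentrations are clipped at 0.
    """
    rng = np.random.default_rng(params.seed)
    phenotype = _draw_phenotypes(params, rng)
    subjects = list(phenotype.index)
    arms = [CONTROL, *params.substrates]

    base_ab, base_prop = 11.0, 0.8
    records = []
    for subject in subjects:
        u = rng.normal(0.0, params.subject_sd)
        for arm in arms:
            if arm == CONTROL:
                delta = 0.0
            elif phenotype.loc[subject, arm] == "R":
                delta = params.delta_ab_responder
            else:
                delta = params.delta_ab_nonresponder
            for rep in range(1, params.replicates + 1):
                for tp in params.timepoints_h:
                    total = base_ab + delta + u + rng.normal(0.0, params.residual_sd)
                    total = max(total, 0.0)
                    frac = np.clip(rng.normal(0.65, 0.03), 0.4, 0.9)
                    acetate = frac * total
                    butyrate = (1.0 - frac) * total
                    prop = max(base_prop + rng.normal(0.0, 0.3), 0.0)
                    ph = np.clip(7.4 - 0.07 * total + rng.normal(0.0, 0.15), 3.8, 9.2)
                    pct = np.clip(8.0 + 2.2 * total + rng.normal(0.0, 4.0), 0.0, 100.0)
                    records.append(
                        (subject, arm, rep, tp, acetate, butyrate, prop, ph, pct)
                    )
    scfa = pd.DataFrame(
        records,
        columns=[
            "subject_id", "treatment", "replicate", "timepoint_h",
            "acetate_mM", "butyrate_mM", "propionate_mM", "pH", "pct_fermented",
        ],
    )
    return scfa, TruthTable(phenotype=phenotype)


def simulate_gene_catalog(
    params: SimParams, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, TruthTable]:
    """Generate an annotated gene catalog with planted clusters.

    Each planted cluster spec occupies its own contig, flanked by
    non-signature genes only, so cluster detection must recover it
    membership-exactly.  Remaining contigs carry background genes whose
    signatures are drawn at the configured rates, including decoy
    CAZymes annotated with blacklisted enzyme names.  A configurable
    number of background whitelist-family CAZymes are designated decoy
    qPCR targets (assayed but phenotype-independent).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    if truth is None:
        truth = TruthTable(phenotype=_draw_phenotypes(params, rng))
    specs = params.planted_cgc_specs
    if len(specs) > params.n_contigs:
        raise ValueError("more planted specs than contigs")

    gene_counter = 0

    def next_gid() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"GID_{gene_counter:05d}"

    rows = []
    planted_genes: dict[str, list[str]] = {s: [] for s in params.substrates}
    planted_cgcs: list[dict] = []
    decoy_candidates: list[str] = []

    for c in range(params.n_contigs):
        contig = f"contig_{c + 1:03d}"
        spec = specs[c] if c < len(specs) else None
        n_genes = params.genes_per_contig
        # decide per-position signature plan
        plan: list[tuple[str, str | None]] = []  # (signature, family token)
        if spec is not None:
            # planted contigs carry no other signature genes, so flanks
            # only keep the cluster off the contig edge when room allows
            avail = n_genes - spec.span
            flank = min(6, avail // 2)
            start = int(rng.integers(flank, n_genes - spec.span - flank + 1))
            planted_positions: dict[int, str] = {}
            pos = start
            for i, token in enumerate(spec.layout):
                planted_positions[pos] = token
                pos += 1 + (spec.gap if i < len(spec.layout) - 1 else 0)
            for i in range(n_genes):
                token = planted_positions.get(i)
                if token is None:
                    plan.append(("NONE", None))
                elif token in ("TC", "TF"):
                    plan.append((token, None))
                else:
                    plan.append(("CAZYME", token))
        else:
            for i in range(n_genes):
                r = rng.random()
                if r < params.background_cazyme_rate:
                    if rng.random() < 0.5:
                        fam, _, _ = _DECOY_EC[int(rng.integers(len(_DECOY_EC)))]
                        plan.append(("CAZYME", f"decoy:{fam}"))
                    else:
                        fam = _BACKGROUND_FAMILIES[
                            int(rng.integers(len(_BACKGROUND_FAMILIES)))
                        ]
                        plan.append(("CAZYME", fam))
                elif r < params.background_cazyme_rate + params.background_tc_rate:
                    plan.append(("TC", None))
                elif (
                    r
                    < params.background_cazyme_rate
                    + params.background_tc_rate
                    + params.background_tf_rate
                ):
                    plan.append(("TF", None))
                else:
                    plan.append(("NONE", None))

        # lay genes down the contig with 1-based inclusive coordinates
        pos_bp = 1
        contig_rows = []
        for i, (sig, fam_token) in enumerate(plan):
            length = int(rng.integers(200, 800)) * 3
            start_bp = pos_bp
            end_bp = pos_bp + length - 1
            pos_bp = end_bp + 1 + int(rng.integers(20, 200))
            gid = next_gid()
            strand = "+" if rng.random() < 0.5 else "-"
            fams, ecs, names = "", "", ""
            taxon = _TAXA[int(rng.integers(len(_TAXA)))]
            if sig == "CAZYME":
                if fam_token and fam_token.startswith("decoy:"):
                    fam = fam_token.split(":", 1)[1]
                    match = [d for d in _DECOY_EC if d[0] == fam]
                    _, ec, name = match[int(rng.integers(len(match)))]
                    fams, ecs, names = fam, ec, name
                elif fam_token in _CAZY_EC:
                    ec, name = _CAZY_EC[fam_token]
                    fams, ecs, names = fam_token, ec, name
                else:
                    fams = fam_token or "GH13"
                    ecs, names = "3.2.1.1", "alpha-amylase"
            if spec is not None and sig != "NONE":
                taxon = "Bifidobacterium adolescentis"
            contig_rows.append(
                {
                    "gene_id": gid,
                    "contig_id": contig,
                    "order_index": i,
                    "start_bp": start_bp,
                    "end_bp": end_bp,
                    "strand": strand,
                    "signature": sig,
                    "cazy_families": fams,
                    "ec_numbers": ecs,
                    "ec_names": names,
                    "taxon": taxon,
                }
            )
            if spec is None and sig == "CAZYME" and fams in _CAZY_EC:
                decoy_candidates.append(gid)
        rows.extend(contig_rows)

        if spec is not None:
            sig_rows = [r for r in contig_rows if r["signature"] != "NONE"]
            first = min(r["order_index"] for r in sig_rows)
            last = max(r["order_index"] for r in sig_rows)
            member_ids = [
                r["gene_id"] for r in contig_rows if first <= r["order_index"] <= last
            ]
            target_ids = [r["gene_id"] for r in sig_rows]
            planted_genes[spec.substrate].extend(target_ids)
            planted_cgcs.append(
                {
                    "substrate": spec.substrate,
                    "contig_id": contig,
                    "member_gene_ids": member_ids,
                    "target_gene_ids": target_ids,
                }
            )

    catalog = pd.DataFrame(rows, columns=CATALOG_COLUMNS)

    # designate decoy qPCR targets among background whitelist-family CAZymes;
    # plant extras if the background produced too few
    need = params.n_decoy_targets - len(decoy_candidates)
    if need > 0:
        none_idx = catalog.index[
            (catalog["signature"] == "NONE")
            & (~catalog["contig_id"].isin([p["contig_id"] for p in planted_cgcs]))
        ]
        chosen = rng.choice(none_idx.to_numpy(), size=need, replace=False)
        for idx in chosen:
            fam = ["GH43", "GH32"][int(rng.integers(2))]
            ec, name = _CAZY_EC[fam]
            catalog.loc[idx, ["signature", "cazy_families", "ec_numbers", "ec_names"]] = [
                "CAZYME", fam, ec, name,
            ]
            decoy_candidates.append(catalog.loc[idx, "gene_id"])
    decoys = sorted(decoy_candidates)[: params.n_decoy_targets]

    truth.planted_genes = planted_genes
    truth.planted_cgcs = planted_cgcs
    truth.decoy_genes = decoys
    return catalog, truth


def simulate_counts(
    catalog: pd.DataFrame, truth: TruthTable, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate gene x sample NB counts with a planted responder fold change.

    Samples are subject x substrate fermentations.  Genes planted for a
    substrate have expected log2 fold change ``planted_log2fc`` in that
    substrate's responder samples.  Returns (counts, sample metadata).
    """
    if catalog.empty:
        raise ValueError("catalog must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    subjects = truth.subjects()
    samples = []
    for subject in subjects:
        for substrate in params.substrates:
            samples.append(
                {
                    "sample_id": f"{subject}_{substrate}",
                    "subject_id": subject,
                    "substrate": substrate,
                    "phenotype": truth.phenotype.loc[subject, substrate],
                }
            )
    meta = pd.DataFrame(samples).set_index("sample_id")

    genes = catalog["gene_id"].to_numpy()
    n_genes, n_samples = genes.size, len(meta)
    base = rng.lognormal(np.log(params.count_base_mean), 1.0, size=n_genes)
    lo, hi = params.count_depth_range
    depth = rng.uniform(lo, hi, size=n_samples)

    fc = np.ones((n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    planted_members = {
        sub: set(gids) for sub, gids in truth.planted_genes.items()
    }
    # fold change also applies to gap genes inside planted clusters (the
    # whole locus rides with the responder strain)
    for cluster in truth.planted_cgcs:
        planted_members.setdefault(cluster["substrate"], set()).update(
            cluster["member_gene_ids"]
        )
    for j, (_, srow) in enumerate(meta.iterrows()):
        if srow["phenotype"] != "R":
            continue
        for g in planted_members.get(srow["substrate"], ()):
            fc[gene_pos[g], j] = 2.0**params.planted_log2fc

    mean = base[:, None] * depth[None, :] * fc
    alpha = params.nb_dispersion
    if alpha < 1e-8:
        counts = rng.poisson(mean)
    else:
        n_nb = 1.0 / alpha
        p_nb = n_nb / (n_nb + mean)
        counts = rng.negative_binomial(n_nb, p_nb)
    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    counts_df.index.name = "gene_id"
    return counts_df, meta.reset_index()


def simulate_qpcr(
    truth: TruthTable, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate baseline qPCR screening of target genes.

    Target genes are the planted cluster members plus decoys.  For a
    substrate's planted genes, responders draw log10 copies from
    Normal(mu_R, sd); non-responders are non-detect with probability
    1 - nonresponder_detect_prob, otherwise draw low copies.  Decoy
    targets are phenotype-independent.  CT values invert the configured
    standard curve plus Gaussian noise; non-detect wells carry NaN CT.

    Returns (true copy-number matrix [subjects x targets], well-level
    CT table, standard-curve dilution series per target).
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 3]))
    subjects = truth.subjects()
    gene_substrate = {
        g: sub for sub, gids in truth.planted_genes.items() for g in gids
    }
    targets = [g for sub in params.substrates for g in truth.planted_genes.get(sub, [])]
    targets += list(truth.decoy_genes)

    copies = pd.DataFrame(0.0, index=pd.Index(subjects, name="subject_id"),
                          columns=targets)
    for g in targets:
        sub = gene_substrate.get(g)
        for s in subjects:
            if sub is None:  # decoy: same distribution for everyone
                log10c = rng.normal(2.0, params.qpcr_sd)
            elif truth.phenotype.loc[s, sub] == "R":
                log10c = rng.normal(params.qpcr_mu_log10_responder, params.qpcr_sd)
            else:
                if rng.random() >= params.nonresponder_detect_prob:
                    copies.loc[s, g] = 0.0
                    continue
                log10c = rng.normal(params.qpcr_mu_log10_nonresponder, params.qpcr_sd)
            copies.loc[s, g] = 10.0**log10c

    wells = []
    for g in targets:
        for s in subjects:
            c = copies.loc[s, g]
            for rep in (1, 2):
                if c <= 0:
                    ct = np.nan
                else:
                    ct = (
                        params.qpcr_intercept
                        + params.qpcr_slope * np.log10(c)
                        + rng.normal(0.0, params.qpcr_ct_sd)
                    )
                wells.append(
                    {"sample_id": s, "target_gene": g, "well_replicate": rep, "ct": ct}
                )
    wells_df = pd.DataFrame(wells)

    standards = []
    for g in targets:
        for level in range(2, 8):  # 10-fold series, 1e2 .. 1e7 copies
            c = 10.0**level
            ct = (
                params.qpcr_intercept
                + params.qpcr_slope * level
                + rng.normal(0.0, params.qpcr_ct_sd)
            )
            standards.append({"target_gene": g, "copies": c, "ct": ct})
    standards_df = pd.DataFrame(standards)
    return copies, wells_df, standards_df


def simulate_cohort(params: SimParams):
    """Run the full generator: SCFA, catalog, counts, qPCR, truth."""
    scfa, truth = simulate_scfa(params)
    catalog, truth = simulate_gene_catalog(params, truth)
    counts, samples = simulate_counts(catalog, truth, params)
    copies, wells, standards = simulate_qpcr(truth, params)
    return {
        "scfa": scfa,
        "catalog": catalog,
        "counts": counts,
        "samples": samples,
        "copies": copies,
        "wells": wells,
        "standards": standards,
        "truth": truth,
    }
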