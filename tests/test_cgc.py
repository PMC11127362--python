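"""Cluster detection against a brute-force oracle, plus the filter cascade."""

import numpy as np
import pandas as pd
import pytest

from prebioresponse.cgc import (
    CgcParams,
    SubstrateSpec,
    cluster_copy_number,
    clusters_for_genes,
    find_cgcs,
    responder_association_filter,
    substrate_gene_filter,
)


def catalog_from_signatures(signatures, contig="c1", start_gid=1):
    """Build a minimal catalog from a list of signature strings."""
    rows = []
    pos = 1
    for i, sig in enumerate(signatures):
        rows.append(
            {
                "gene_id": f"g{start_gid + i}",
                "contig_id": contig,
                "order_index": i,
                "start_bp": pos,
                "end_bp": pos + 899,
                "strand": "+",
                "signature": sig,
                "cazy_families": "GH43" if sig == "CAZYME" else "",
                "ec_numbers": "",
                "ec_names": "",
                "taxon": "",
            }
        )
        pos += 1000
    return pd.DataFrame(rows)


def brute_force_cgcs(signatures, max_gap=5):
    """Independent enumeration: link signature genes pairwise, then chain.

    Two signature genes are linked when at most ``max_gap`` non-signature
    genes lie between them; connected components of the link graph are
    candidate clusters, kept when they contain a CAZyme and a TC.
    Returns member index tuples (span inclusive of gap genes).
    """
    sig_idx = [i for i, s in enumerate(signatures) if s != "NONE"]
    parent = {i: i for i in sig_idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in sig_idx:
        for b in sig_idx:
            if a < b:
                between = [k for k in range(a + 1, b) if signatures[k] == "NONE"]
                sigs_between = [k for k in range(a + 1, b) if signatures[k] != "NONE"]
                if not sigs_between and len(between) <= max_gap:
                    parent[find(a)] = find(b)
    comps = {}
    for i in sig_idx:
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        sigs = [signatures[i] for i in members]
        if "CAZYME" in sigs and "TC" in sigs:
            lo, hi = min(members), max(members)
            out.append(tuple(range(lo, hi + 1)))
    return sorted(out)


class TestFindCgcs:
    def test_gap_at_threshold_joins(self):
        sigs = ["CAZYME"] + ["NONE"] * 5 + ["TC"]
        cgcs = find_cgcs(catalog_from_signatures(sigs))
        assert len(cgcs) == 1
        assert cgcs["member_gene_ids"].iloc[0] == [f"g{i}" for i in range(1, 8)]

    def test_gap_above_threshold_splits(self):
        sigs = ["CAZYME"] + ["NONE"] * 6 + ["TC"]
        assert find_cgcs(catalog_from_signatures(sigs)).empty

    def test_composition_requirements(self):
        # two CAZymes without a transporter do not form a cluster
        assert find_cgcs(catalog_from_signatures(["CAZYME", "CAZYME"])).empty
        # TF keeps the run alive but cannot satisfy the TC requirement
        assert find_cgcs(catalog_from_signatures(["CAZYME", "TF", "CAZYME"])).empty
        got = find_cgcs(catalog_from_signatures(["CAZYME", "TF", "TC"]))
        assert len(got) == 1 and got["n_tf"].iloc[0] == 1

    def test_empty_catalog(self):
        assert find_cgcs(catalog_from_signatures([])).empty

    def test_unsorted_catalog_rejected(self):
        cat = catalog_from_signatures(["CAZYME", "TC"])
        with pytest.raises(ValueError, match="sorted"):
            find_cgcs(cat.iloc[::-1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        frames = []
        expected = []
        for c in range(50):
            n = int(rng.integers(5, 40))
            sigs = list(
                rng.choice(
                    ["CAZYME", "TC", "TF", "NONE"], size=n, p=[0.1, 0.1, 0.05, 0.75]
                )
            )
            cat = catalog_from_signatures(sigs, contig=f"c{c:03d}",
                                          start_gid=1000 * c)
            frames.append(cat)
            for span in brute_force_cgcs(sigs, max_gap=5):
                expected.append(tuple(cat["gene_id"].iloc[list(span)]))
        catalog = pd.concat(frames, ignore_index=True)
        got = sorted(
            tuple(m) for m in find_cgcs(catalog, CgcParams(max_gap=5))["member_gene_ids"]
        )
        assert got == sorted(expected)

    def test_contig_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(3)
        frames = [
            catalog_from_signatures(
                list(rng.choice(["CAZYME", "TC", "NONE"], size=20, p=[0.15, 0.15, 0.7])),
                contig=f"c{c}", start_gid=100 * c,
            )
            for c in range(6)
        ]
        cat = pd.concat(frames, ignore_index=True)
        shuffled = pd.concat(frames[::-1], ignore_index=True)
        a = find_cgcs(cat)
        b = find_cgcs(shuffled)
        assert sorted(map(tuple, a["member_gene_ids"])) == sorted(
            map(tuple, b["member_gene_ids"])
        )

    def test_recovers_planted_clusters(self, small_cohort):
        truth = small_cohort["truth"]
        found = [tuple(m) for m in find_cgcs(small_cohort["catalog"])["member_gene_ids"]]
        for planted in truth.planted_cgcs:
            assert tuple(planted["member_gene_ids"]) in found


def _annotated(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "cazy_families", "ec_numbers", "ec_names"]
    )


class TestSubstrateFilter:
    xos = SubstrateSpec.default("XOS")

    def test_whitelisted_xylosidase_kept(self):
        genes = _annotated([("g1", "GH43", "3.2.1.37", "beta-xylosidase")])
        assert substrate_gene_filter(genes, self.xos)["gene_id"].tolist() == ["g1"]

    def test_blacklisted_glucosidase_removed(self):
        genes = _annotated([("g1", "GH3", "3.2.1.21", "beta-glucosidase")])
        assert substrate_gene_filter(genes, self.xos).empty

    def test_subfamily_matches_root(self):
        genes = _annotated([("g1", "GH43_12", "3.2.1.37", "beta-xylosidase")])
        assert len(substrate_gene_filter(genes, self.xos)) == 1

    def test_non_whitelisted_family_dropped(self):
        genes = _annotated([("g1", "GH13", "3.2.1.1", "alpha-amylase")])
        assert substrate_gene_filter(genes, self.xos).empty

    def test_empty_input(self):
        empty = _annotated([])
        assert substrate_gene_filter(empty, self.xos).empty

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ValueError, match="unknown substrate"):
            SubstrateSpec.default("GOS")

    def test_whitelist_enlargement_is_monotone(self):
        rng = np.random.default_rng(0)
        fams = ["GH43", "GH13", "GH32", "GH3"]
        genes = _annotated(
            [
                (f"g{i}", fams[rng.integers(4)], "", "")
                for i in range(30)
            ]
        )
        small = SubstrateSpec("XOS", frozenset({"GH43"}))
        big = SubstrateSpec("XOS", frozenset({"GH43", "GH13"}))
        kept_small = set(substrate_gene_filter(genes, small)["gene_id"])
        kept_big = set(substrate_gene_filter(genes, big)["gene_id"])
        assert kept_small <= kept_big


class TestResponderAssociationFilter:
    def test_sign_and_significance_gates(self):
        da = pd.DataFrame(
            {"log2fc": [2.0, -2.0, 1.0, 0.5], "q": [0.01, 0.01, 0.2, np.nan]},
            index=["up_sig", "down_sig", "up_ns", "untested"],
        )
        assert responder_association_filter(da) == ["up_sig"]


class TestClustersForGenes:
    def _cgcs(self):
        return pd.DataFrame(
            {
                "cgc_id": ["CGC1", "CGC2"],
                "contig_id": ["c1", "c2"],
                "member_gene_ids": [[f"m{i}" for i in range(10)], ["a1", "a2", "a3"]],
                "n_cazyme": [2, 1],
                "n_tc": [1, 1],
                "n_tf": [0, 0],
                "start_bp": [1, 1],
                "end_bp": [9999, 2999],
            }
        )

    def test_whole_cluster_selected_from_one_gene(self):
        selected, singletons = clusters_for_genes(["m4"], self._cgcs(), "XOS")
        assert len(selected) == 1
        assert selected["member_gene_ids"].iloc[0] == [f"m{i}" for i in range(10)]
        assert singletons == []

    def test_substrate_naming_in_discovery_order(self):
        selected, _ = clusters_for_genes(["m0", "a2"], self._cgcs(), "XOS")
        assert selected["cgc_id"].tolist() == ["XCGC1", "XCGC2"]

    def test_no_retained_genes_is_empty_not_error(self):
        selected, singletons = clusters_for_genes([], self._cgcs(), "FOS")
        assert selected.empty and singletons == []

    def test_orphan_genes_reported_as_singletons(self):
        _, singletons = clusters_for_genes(["zz"], self._cgcs(), "INU")
        assert singletons == ["zz"]


class TestClusterCopyNumber:
    def test_arithmetic_and_nondetect(self):
        cn = pd.DataFrame(
            {"g1": [1e3, 0.0], "g2": [1e3, 0.0], "g3": [0.0, 0.0]},
            index=["s1", "s2"],
        )
        row = {"cgc_id": "XCGC1", "member_gene_ids": ["g1", "g2", "g3"]}
        totals = cluster_copy_number(cn, row)
        assert totals.loc["s1"] == pytest.approx(2e3)
        assert totals.loc["s2"] == 0.0

    def test_matches_row_sum_oracle(self):
        rng = np.random.default_rng(4)
        cn = pd.DataFrame(
            rng.uniform(0, 1e4, size=(8, 5)),
            columns=[f"g{i}" for i in range(5)],
        )
        row = {"cgc_id": "X", "member_gene_ids": ["g0", "g2", "g4"]}
        np.testing.assert_allclose(
            cluster_copy_number(cn, row),
            cn[["g0", "g2", "g4"]].to_numpy().sum(axis=1),
        )

    def test_unassayed_cluster_rejected(self):
        cn = pd.DataFrame({"g1": [1.0]})
        with pytest.raises(ValueError, match="no assayed"):
            cluster_copy_number(cn, {"cgc_id": "X", "member_gene_ids": ["zz"]})
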