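"""Reference interactome loading and Bayesian LLS curve scoring."""

import math

import numpy as np
import pytest

from scnet import (
    GoldStandard,
    compute_lls_curve,
    load_interactome,
    rank_links,
    save_network,
)
from scnet.reference import canonical_pair


def brute_force_lls(links, gold, bin_size):
    """Independent per-bin counter: the oracle for compute_lls_curve."""
    evaluable = [
        canonical_pair(a, b)
        for a, b, _ in links
        if a in gold.gene_universe and b in gold.gene_universe
    ]
    prior_odds = gold.prior_odds
    out = []
    for start in range(0, len(evaluable), bin_size):
        chunk = evaluable[start : start + bin_size]
        n_pos = sum(1 for pair in chunk if pair in gold.positives)
        n_neg = len(chunk) - n_pos
        if n_pos == 0:
            lls = -math.inf
        elif n_neg == 0:
            lls = math.inf
        else:
            lls = math.log((n_pos / n_neg) / prior_odds)
        out.append((len(chunk), n_pos, n_neg, lls))
    return out


def random_gold_and_links(rng, n_genes=20, n_links=120):
    genes = [f"G{i:02d}" for i in range(n_genes)]
    pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
    k = int(rng.integers(3, len(pairs) - 1))
    pos_idx = rng.choice(len(pairs), size=k, replace=False)
    gold = GoldStandard.from_pairs([pairs[i] for i in pos_idx], genes)
    link_idx = rng.choice(len(pairs), size=min(n_links, len(pairs)), replace=False)
    scores = rng.random(len(link_idx))
    links = rank_links(
        [(pairs[i][0], pairs[i][1], s) for i, s in zip(link_idx, scores)]
    )
    return gold, links


class TestLoadInteractome:
    def test_dedup_and_self_loop(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t1.5\nB\tA\t1.5\nA\tA\t2.0\n")
        with caplog.at_level("WARNING"):
            g = load_interactome(path)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 1.5
        assert any("self-loop" in r.message for r in caplog.records)

    def test_coding_gene_filter(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t1\nB\tC\t2\nC\tD\t3\n")
        g = load_interactome(path, coding_genes={"A", "B", "C"})
        assert set(g.edges) == {("A", "B"), ("B", "C")}

    def test_roundtrip_identity(self, tmp_path, small_ref):
        path = tmp_path / "net.tsv"
        save_network(small_ref, path)
        loaded = load_interactome(path)
        assert {tuple(sorted(e)) for e in loaded.edges} == {
            tuple(sorted(e)) for e in small_ref.edges
        }
        for u, v in small_ref.edges:
            assert loaded[u][v]["weight"] == pytest.approx(small_ref[u][v]["weight"])

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t1.0\nA\tB\tnot_a_number\n")
        with pytest.raises(ValueError, match="line 2"):
            load_interactome(path)

    def test_nonpositive_weight_is_hard_error(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\t-1.0\n")
        with pytest.raises(ValueError, match="nonpositive"):
            load_interactome(path)

    def test_two_column_needs_default_weight(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("A\tB\nB\tC\n")
        with pytest.raises(ValueError):
            load_interactome(path)
        g = load_interactome(path, default_weight=1.0)
        assert g.number_of_edges() == 2

    def test_header_autodetected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("geneA\tgeneB\tweight\nA\tB\t1.5\n")
        g = load_interactome(path)
        assert set(g.edges) == {("A", "B")}


class TestLLSCurve:
    def test_hand_computed_bin(self):
        """10 genes, 10 positives (prior odds 10/35); bin of 5 with 3 pos."""
        genes = [f"G{i}" for i in range(10)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(pairs[:10], genes)
        assert gold.prior_odds == pytest.approx(10 / 35)
        links = [(a, b, 1.0) for a, b in pairs[:3]] + [(a, b, 0.5) for a, b in pairs[20:22]]
        bins = compute_lls_curve(links, gold, bin_size=5)
        assert len(bins) == 1
        assert (bins[0].n_pos, bins[0].n_neg) == (3, 2)
        assert bins[0].lls == pytest.approx(math.log((3 / 2) / (10 / 35)))
        assert bins[0].lls == pytest.approx(1.6582, abs=1e-4)

    def test_bin_at_prior_odds_scores_zero(self):
        """A bin whose pos:neg ratio equals the prior odds has LLS 0."""
        genes = [f"G{i}" for i in range(5)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(pairs[:5], genes)  # prior odds 5/5 = 1
        links = [(*pairs[0], 2.0), (*pairs[7], 1.0)]  # 1 pos, 1 neg
        bins = compute_lls_curve(links, gold, bin_size=2)
        assert bins[0].lls == pytest.approx(0.0)

    def test_all_positive_bin_flagged_infinite(self):
        genes = [f"G{i}" for i in range(5)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(pairs[:5], genes)
        bins = compute_lls_curve([(a, b, 1.0) for a, b in pairs[:5]], gold, bin_size=5)
        assert bins[0].lls == math.inf
        assert bins[0].degenerate

    def test_links_outside_universe_are_skipped(self):
        genes = ["A", "B", "C", "D"]
        gold = GoldStandard.from_pairs([("A", "B")], genes)
        links = [("A", "B", 3.0), ("A", "ZZ", 2.0), ("C", "D", 1.0)]
        bins = compute_lls_curve(links, gold, bin_size=2)
        assert len(bins) == 1
        assert bins[0].n_links == 2  # the ZZ link never counted

    def test_final_partial_bin_reported(self):
        genes = [f"G{i}" for i in range(6)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(pairs[:6], genes)
        bins = compute_lls_curve([(a, b, 1.0) for a, b in pairs[:7]], gold, bin_size=5)
        assert [b.n_links for b in bins] == [5, 2]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gold, links = random_gold_and_links(rng)
        bin_size = int(rng.integers(1, 30))
        bins = compute_lls_curve(links, gold, bin_size=bin_size)
        oracle = brute_force_lls(links, gold, bin_size)
        assert len(bins) == len(oracle)
        for b, (n_links, n_pos, n_neg, lls) in zip(bins, oracle):
            assert (b.n_links, b.n_pos, b.n_neg) == (n_links, n_pos, n_neg)
            if math.isfinite(lls):
                assert b.lls == pytest.approx(lls)
            else:
                assert b.lls == lls and b.degenerate

    def test_monotone_enrichment_when_positives_first(self):
        """All positives ranked before all negatives -> non-increasing LLS."""
        rng = np.random.default_rng(3)
        genes = [f"G{i:02d}" for i in range(15)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        pos = pairs[:40]
        gold = GoldStandard.from_pairs(pos, genes)
        neg = [p for p in pairs if p not in set(pos)]
        links = [(a, b, 2.0 + i) for i, (a, b) in enumerate(reversed(pos))]
        links += [(a, b, 1.0 - 0.001 * i) for i, (a, b) in enumerate(neg)]
        bins = compute_lls_curve(rank_links(links), gold, bin_size=10)
        finite = [b.lls for b in bins]
        assert all(x >= y for x, y in zip(finite, finite[1:]))

    def test_random_ranking_mean_lls_near_zero(self):
        """Uniformly random rankings carry no information: mean bin LLS ~ 0."""
        rng = np.random.default_rng(11)
        genes = [f"G{i:02d}" for i in range(22)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(
            [pairs[i] for i in rng.choice(len(pairs), size=100, replace=False)], genes
        )
        means = []
        for _ in range(60):
            idx = rng.permutation(len(pairs))
            links = [(pairs[i][0], pairs[i][1], 0.0) for i in idx]
            bins = compute_lls_curve(links, gold, bin_size=50)
            means.extend(b.lls for b in bins if not b.degenerate)
        assert abs(np.mean(means)) < 0.1


class TestGoldStandard:
    def test_prior_from_counts(self):
        genes = [f"G{i}" for i in range(10)]
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        gold = GoldStandard.from_pairs(pairs[:9], genes)
        assert gold.prior == pytest.approx(9 / 45)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            GoldStandard(frozenset(), frozenset("ABC"))

    def test_rank_links_rejects_self_pairs_and_breaks_ties(self):
        with pytest.raises(ValueError):
            rank_links([("A", "A", 1.0)])
        links = rank_links([("C", "B", 1.0), ("B", "A", 1.0), ("D", "A", 2.0)])
        assert links == [("A", "D", 2.0), ("A", "B", 1.0), ("B", "C", 1.0)]
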