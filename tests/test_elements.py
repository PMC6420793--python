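"""Scanner semantics, distances, gene classification and feature comparison."""

import re

import numpy as np
import pandas as pd
import pytest

from rescuemap.elements import (ScanParams, assign_response_classes,
                                compare_element_features, element_gene_distance,
                                find_ggaa_microsatellites, reverse_complement,
                                scan_ets_motif)

PARAMS = ScanParams()


# --- independent regex oracles ---------------------------------------------

def regex_ms_oracle(seq, min_repeats=4, max_gap=4):
    """Regex-based microsatellite caller used only as a cross-check."""
    out = []
    for unit, strand in (("GGAA", "+"), ("TTCC", "-")):
        pat = re.compile(f"(?:{unit})+(?:[ACGTN]{{1,{max_gap}}}(?:{unit})+)*")
        for m in pat.finditer(seq):
            runs = [len(r.group(0)) // 4
                    for r in re.finditer(f"(?:{unit})+", m.group(0))]
            total = sum(runs)
            if total >= min_repeats:
                out.append((m.start(), m.end(), strand, total, max(runs)))
    return sorted(out)


def regex_ets_oracle(seq, motif="ACMGGAARY"):
    lookup = {"A": "A", "C": "C", "G": "G", "T": "T", "M": "[AC]", "R": "[AG]",
              "Y": "[CT]", "K": "[GT]", "S": "[CG]", "W": "[AT]"}
    out = []
    for strand, m in (("+", motif), ("-", reverse_complement(motif))):
        pat = re.compile("(?=(" + "".join(lookup[c] for c in m) + "))")
        out += [(mm.start(), mm.start() + len(m), strand) for mm in pat.finditer(seq)]
    return sorted(out)


def _random_ggaa_rich(rng, length=2000):
    tokens = ["A", "C", "G", "T", "GGAA", "TTCC", "GGAAGGAA", "ACAGGAAGC"]
    probs = [0.23, 0.23, 0.23, 0.23, 0.03, 0.02, 0.02, 0.01]
    parts, size = [], 0
    while size < length:
        t = rng.choice(tokens, p=probs)
        parts.append(t)
        size += len(t)
    return "".join(parts)[:length]


class TestMicrosatelliteScanner:
    def test_single_run(self):
        df = find_ggaa_microsatellites("GGAA" * 4, PARAMS)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row.start, row.end, row.total_repeats, row.max_consecutive) == (0, 16, 4, 4)

    def test_gap_merge(self):
        seq = "GGAA" * 4 + "TT" + "GGAA" * 4
        df = find_ggaa_microsatellites(seq, PARAMS)
        assert len(df) == 1
        assert df.iloc[0].total_repeats == 8
        assert df.iloc[0].max_consecutive == 4

    def test_gap_beyond_limit_not_merged(self):
        seq = "GGAA" * 4 + "T" * 5 + "GGAA" * 4
        df = find_ggaa_microsatellites(seq, PARAMS)
        assert len(df) == 2

    def test_minus_strand_reported(self):
        df = find_ggaa_microsatellites("TTCC" * 5, PARAMS)
        assert len(df) == 1 and df.iloc[0].strand == "-"

    def test_below_min_repeats_dropped(self):
        assert find_ggaa_microsatellites("GGAA" * 3, PARAMS).empty

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for _ in range(300):
            seq = _random_ggaa_rich(rng)
            df = find_ggaa_microsatellites(seq, PARAMS)
            got = sorted(zip(df.start, df.end, df.strand, df.total_repeats,
                             df.max_consecutive))
            assert got == regex_ms_oracle(seq)

    def test_case_insensitive(self):
        a = find_ggaa_microsatellites("ggaaGGaaGGAAggaa", PARAMS)
        b = find_ggaa_microsatellites("GGAA" * 4, PARAMS)
        pd.testing.assert_frame_equal(a, b)

    def test_reverse_complement_mirrors_calls(self, rng):
        seq = _random_ggaa_rich(rng, 500)
        fwd = find_ggaa_microsatellites(seq, PARAMS)
        rev = find_ggaa_microsatellites(reverse_complement(seq), PARAMS)
        L = len(seq)
        mirrored = sorted((L - e, L - s, {"+": "-", "-": "+"}[st])
                          for s, e, st in zip(fwd.start, fwd.end, fwd.strand))
        assert mirrored == sorted(zip(rev.start, rev.end, rev.strand))

    def test_min_repeats_monotonicity(self, rng):
        seq = _random_ggaa_rich(rng)
        counts = [len(find_ggaa_microsatellites(seq, ScanParams(min_repeats=k)))
                  for k in (2, 4, 6, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_character_position_reported(self):
        with pytest.raises(ValueError, match="position 4"):
            find_ggaa_microsatellites("GGAAX", PARAMS)


class TestEtsScanner:
    def test_plus_strand_instance(self):
        df = scan_ets_motif("ACAGGAAGC", PARAMS)
        assert len(df) == 1 and df.iloc[0].strand == "+"

    def test_minus_strand_instance(self):
        df = scan_ets_motif("GCTTCCTGT", PARAMS)
        assert len(df) == 1 and df.iloc[0].strand == "-"

    def test_iupac_violation_rejected(self):
        assert scan_ets_motif("ACTGGAAGC", PARAMS).empty

    def test_matches_regex_oracle_on_random_sequences(self, rng):
        for _ in range(300):
            seq = _random_ggaa_rich(rng)
            df = scan_ets_motif(seq, PARAMS)
            assert sorted(zip(df.start, df.end, df.strand)) == regex_ets_oracle(seq)

    def test_offset_match_not_masked_by_prefix(self):
        seq = "ACACAGGAAGC"  # match at 2; the AC prefix must not mask it
        df = scan_ets_motif(seq, PARAMS)
        assert list(df.start) == [2]


class TestDistance:
    @pytest.mark.parametrize("tss,expected", [(1050, 0), (1600, 500), (400, 600),
                                              (1000, 0), (1099, 0)])
    def test_edge_conventions(self, tss, expected):
        assert element_gene_distance(1000, 1100, tss) == expected

    def test_degenerate_element_rejected(self):
        with pytest.raises(ValueError):
            element_gene_distance(100, 100, 50)


class TestClassAssignment:
    def _setup(self):
        genes = pd.DataFrame({
            "chrom": ["c1", "c1", "c1", "c2", "c1"],
            "tss": [10_000, 200_000, 400_000, 5_000, 600_000],
            "strand": ["+", "+", "-", "+", "+"],
            "gene": ["gA", "gB", "gC", "gD", "gE"],
        })
        elements = pd.DataFrame({
            "chrom": ["c1", "c1", "c2"],
            "start": [14_999 + 0, 250_000, 5_800],
            "end": [15_100, 250_100, 5_809],
            "strand": ["+", "+", "+"],
            "element_id": ["ms1", "ms2", "ets1"],
            "type": ["ggaa_ms", "ggaa_ms", "ets_motif"],
        })
        # gA: ms at distance 4999 -> promoter-like; gB: ms at 50 kb -> enhancer
        elements.loc[0, "start"] = 14_999
        endo = pd.DataFrame({
            "gene": ["gA", "gB", "gC", "gD", "gE"],
            "log2fc": [2.0, -1.5, 1.0, 1.0, 3.0],
            "padj": [0.01, 0.01, 0.01, 0.01, 0.50],
        })
        return genes, elements, endo

    def test_promoter_enhancer_direction_crossing(self):
        genes, elements, endo = self._setup()
        out = assign_response_classes(genes, elements, endo, PARAMS).set_index("gene")
        assert out.at["gA", "element_class"] == "ms_prom_act"
        assert out.at["gA", "distance"] == 4999
        assert out.at["gB", "element_class"] == "ms_enh_rep"
        assert out.at["gE", "element_class"] == "none"  # not endo-significant

    def test_strand_aware_ets_window(self):
        # minus-strand gene: window extends 5 kb to the right in genome coords
        genes, elements, endo = self._setup()
        genes.loc[genes.gene == "gC", "tss"] = 400_000
        elements = elements[elements.type == "ets_motif"].copy()
        elements.loc[:, ["chrom", "start", "end"]] = ["c1", 400_800, 400_809]
        out = assign_response_classes(genes, elements, endo, PARAMS).set_index("gene")
        assert out.at["gC", "element_class"] == "ets_direct"
        # a plus-strand gene at the same TSS would not see it beyond +1 kb
        genes.loc[genes.gene == "gC", "strand"] = "+"
        genes.loc[genes.gene == "gC", "tss"] = 399_000
        out2 = assign_response_classes(genes, elements, endo, PARAMS).set_index("gene")
        assert out2.at["gC", "element_class"] == "none"

    def test_microsatellite_precedence_over_ets(self):
        genes, elements, endo = self._setup()
        extra = pd.DataFrame({"chrom": ["c1"], "start": [11_000], "end": [11_009],
                              "strand": ["+"], "element_id": ["ets2"],
                              "type": ["ets_motif"]})
        out = assign_response_classes(genes, pd.concat([elements, extra]), endo,
                                      PARAMS).set_index("gene")
        assert out.at["gA", "element_class"].startswith("ms_")

    def test_partition_every_gene_exactly_one_class(self):
        genes, elements, endo = self._setup()
        out = assign_response_classes(genes, elements, endo, PARAMS)
        assert len(out) == len(genes)
        assert out["gene"].is_unique
        assert out["element_class"].notna().all()

    def test_gene_absent_from_endo_table_gets_none(self):
        genes, elements, endo = self._setup()
        out = assign_response_classes(genes, elements, endo[endo.gene != "gA"],
                                      PARAMS).set_index("gene")
        assert out.at["gA", "element_class"] == "none"


class TestFeatureComparison:
    def test_identical_groups(self, rng):
        g = pd.DataFrame({"max_consecutive": rng.integers(4, 30, 20),
                          "total_repeats": rng.integers(4, 40, 20),
                          "fli_enrichment": rng.random(20)})
        out = compare_element_features(g, g.copy()).set_index("feature")
        assert np.allclose(out["p"], 1.0)
        assert np.allclose(out["median_a"], out["median_b"])

    def test_separated_groups_significant(self):
        a = pd.DataFrame({"max_consecutive": [20] * 20})
        b = pd.DataFrame({"max_consecutive": [5] * 20})
        out = compare_element_features(a, b, features=("max_consecutive",))
        assert out["p"].iloc[0] < 0.01

    def test_missing_feature_skipped_with_note(self):
        a = pd.DataFrame({"max_consecutive": [5] * 5, "fli_enrichment": [np.nan] * 5})
        b = pd.DataFrame({"max_consecutive": [6] * 5, "fli_enrichment": [np.nan] * 5})
        out = compare_element_features(a, b).set_index("feature")
        assert "skipped" in out.at["fli_enrichment", "note"]

    def test_type_one_error_rate_controlled(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = pd.DataFrame({"total_repeats": rng.normal(10, 2, 20)})
            b = pd.DataFrame({"total_repeats": rng.normal(10, 2, 20)})
            out = compare_element_features(a, b, features=("total_repeats",))
            rejections += out["p"].iloc[0] < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_element_features(pd.DataFrame(), pd.DataFrame({"x": [1]}))
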