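"""Windows, residue frequencies and motif extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from succinylome.io import SiteRecord
from succinylome.profiling import (
    MotifConfig,
    SiteWindow,
    background_windows,
    extract_windows,
    motif_discovery,
    position_frequency,
    sites_per_protein,
)

from oracles import binomial_upper_tail


class TestSitesPerProtein:
    def test_simple_histogram(self):
        sites = [SiteRecord("P1", 10), SiteRecord("P2", 5), SiteRecord("P2", 9)]
        assert sites_per_protein(sites) == {1: 1, 2: 1}

    def test_histogram_sums_to_protein_count(self):
        rng = np.random.default_rng(0)
        sites = {
            SiteRecord(f"P{rng.integers(20)}", int(p))
            for p in rng.integers(1, 500, size=100)
        }
        hist = sites_per_protein(sites)
        assert sum(hist.values()) == len({s.protein for s in sites})

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sites_per_protein([])


class TestWindows:
    def test_padding_near_n_terminus(self):
        windows = extract_windows([SiteRecord("P1", 2)], {"P1": "MKAAAAAAAAAAA"})
        assert windows[0].window == "XXXXXXXXXMKAAAAAAAAAA"
        assert len(windows[0].window) == 21

    def test_no_padding_in_the_interior(self):
        seq = "A" * 10 + "K" + "C" * 10
        windows = extract_windows([SiteRecord("P1", 11)], {"P1": seq})
        assert windows[0].window == seq
        assert "X" not in windows[0].window

    def test_non_lysine_site_rejected(self):
        with pytest.raises(ValueError, match="not 'K'"):
            extract_windows([SiteRecord("P1", 1)], {"P1": "MKA"})

    def test_out_of_range_position_rejected(self):
        with pytest.raises(IndexError):
            extract_windows([SiteRecord("P1", 9)], {"P1": "MKA"})

    def test_background_covers_every_lysine(self):
        bg = background_windows({"P1": "MKKA"})
        assert [w.site_id for w in bg] == ["P1:K2", "P1:K3"]

    def test_background_superset_of_foreground(self):
        sequences = {"P1": "MKAKCKDKE", "P2": "KKMK"}
        fg = extract_windows([SiteRecord("P1", 2), SiteRecord("P2", 1)], sequences)
        bg = background_windows(sequences)
        assert len(bg) >= len(fg)
        assert {w.site_id for w in fg} <= {w.site_id for w in bg}

    def test_lysine_free_proteome_warns(self):
        with pytest.warns(UserWarning, match="no lysines"):
            assert background_windows({"P1": "MACD"}) == []

    @given(pos=st.integers(min_value=1, max_value=40))
    def test_window_is_the_center_slice_of_the_padded_sequence(self, pos):
        """Inverse property: the stored window equals the ±flank slice of the
        X-padded source sequence, for any site position."""
        rng = np.random.default_rng(pos)
        seq = "".join(rng.choice(list("ACDEFGHILMNPQRSTVWY"), size=40))
        seq = seq[: pos - 1] + "K" + seq[pos:]
        flank = 10
        [w] = extract_windows([SiteRecord("P", pos)], {"P": seq}, flank)
        padded = "X" * flank + seq + "X" * flank
        assert w.window == padded[pos - 1 : pos + 2 * flank]


class TestPositionFrequency:
    def test_pure_foreground_frequency(self):
        fg = [SiteWindow(f"s{i}", "A" * 10 + "K" + "G" + "A" * 9) for i in range(10)]
        bg = [SiteWindow(f"b{i}", "A" * 10 + "K" + "C" + "A" * 9) for i in range(40)]
        pfm = position_frequency(fg, bg)
        assert pfm.fg_freq.loc["G", 1] == 1.0
        assert pfm.bg_freq.loc["G", 1] == 0.0

    def test_identical_sets_have_zero_log_ratio(self):
        windows = [SiteWindow(f"s{i}", "A" * 10 + "K" + "A" * 10) for i in range(5)]
        pfm = position_frequency(windows, list(windows))
        np.testing.assert_allclose(pfm.log2_ratio.to_numpy(), 0.0, atol=1e-12)

    def test_non_pad_frequencies_sum_to_one_per_position(self):
        rng = np.random.default_rng(1)
        residues = list("ACDEFGHILMNPQRSTVWYK")
        make = lambda n: [  # noqa: E731
            SiteWindow(
                f"w{i}",
                "".join(rng.choice(residues, 10)) + "K" + "".join(rng.choice(residues, 10)),
            )
            for i in range(n)
        ]
        pfm = position_frequency(make(30), make(100))
        np.testing.assert_allclose(pfm.fg_freq.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(pfm.bg_freq.sum(axis=0), 1.0, atol=1e-9)

    @pytest.mark.parametrize("k,n", [(3, 10), (10, 10), (1, 25)])
    def test_binomial_p_matches_tail_summation(self, k, n):
        q = 0.2
        fg = [
            SiteWindow(f"s{i}", "A" * 10 + "K" + ("G" if i < k else "C") + "A" * 9)
            for i in range(n)
        ]
        n_bg = 50
        k_bg = int(q * n_bg)
        bg = [
            SiteWindow(f"b{i}", "A" * 10 + "K" + ("G" if i < k_bg else "C") + "A" * 9)
            for i in range(n_bg)
        ]
        pfm = position_frequency(fg, bg)
        expected = binomial_upper_tail(k, n, k_bg / n_bg)
        assert pfm.p_value.loc["G", 1] == pytest.approx(expected, rel=1e-9)


def uniform_windows(rng, n, residues="ACDEFGHILMNPQRSTVWYK"):
    pool = list(residues)
    return [
        SiteWindow(
            f"w{i}",
            "".join(rng.choice(pool, 10)) + "K" + "".join(rng.choice(pool, 10)),
        )
        for i in range(n)
    ]


class TestMotifDiscovery:
    def test_foreground_sampled_from_background_yields_no_motif(self):
        """Mirrors the study outcome: windows drawn from the background's own
        composition carry no extractable consensus."""
        rng = np.random.default_rng(42)
        bg = uniform_windows(rng, 2000)
        fg = [bg[i] for i in rng.choice(len(bg), size=300, replace=False)]
        assert motif_discovery(fg, bg) == []

    def test_identical_foreground_and_background_never_emit(self):
        rng = np.random.default_rng(7)
        windows = uniform_windows(rng, 100)
        assert motif_discovery(windows, list(windows)) == []

    def test_planted_single_position_motif_recovered(self):
        """50 windows with A fixed at −1 (p ≪ 1e-6 by the binomial oracle)
        plus 10 random windows against a uniform background."""
        rng = np.random.default_rng(3)
        bg = uniform_windows(rng, 2000)
        planted = [
            SiteWindow(f"p{i}", w.window[:9] + "A" + w.window[10:])
            for i, w in enumerate(uniform_windows(rng, 50))
        ]
        noise = uniform_windows(rng, 10)
        # oracle check that the construction really clears the threshold
        bg_rate = sum(w.window[9] == "A" for w in bg) / len(bg)
        assert binomial_upper_tail(50, 60, bg_rate) < 1e-6
        motifs = motif_discovery(planted + noise, bg)
        assert len(motifs) >= 1
        assert motifs[0].constraints[-1] == "A"
        assert motifs[0].consensus[9] == "A"
        assert motifs[0].count >= 50

    def test_min_count_larger_than_foreground_yields_empty(self):
        rng = np.random.default_rng(5)
        bg = uniform_windows(rng, 500)
        fg = [SiteWindow(f"s{i}", "A" * 10 + "K" + "A" * 10) for i in range(10)]
        assert motif_discovery(fg, bg, MotifConfig(min_count=21)) == []
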