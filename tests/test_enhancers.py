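"""Marker overlap, window linking, dependency labels, percentage format."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hifmeth._util import format_pct
from hifmeth.containers import MarkerTrack
from hifmeth.enhancers import (
    classify_dependency,
    link_targets,
    overlap_regulatory,
    summarize_probe_dependency,
    EnhancerCandidate,
)


def _track(cell_line, marker, rows):
    return MarkerTrack(
        cell_line=cell_line,
        marker=marker,
        intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
    )


class TestOverlapRegulatory:
    def test_probe_outside_all_intervals_inactive(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [500]}, index=["p1"])
        tracks = [_track("CL1", "DNase", [("chr1", 1000, 2000)])]
        cands, summary = overlap_regulatory(probes, tracks)
        assert not cands[0].active and not cands[0].stringent
        assert summary["n_active"] == 0

    def test_matches_all_pairs_oracle(self):
        """Interval counting agrees with a brute-force membership scan."""
        rng = np.random.default_rng(11)
        probes = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], 50), "pos": rng.integers(0, 100_000, 50)},
            index=[f"p{i}" for i in range(50)],
        )
        tracks = []
        for cl in ("CL1", "CL2"):
            for mk in ("M1", "M2", "M3", "M4", "M5"):
                starts = rng.integers(0, 99_000, 200)
                rows = [
                    (rng.choice(["chr1", "chr2"]), int(s), int(s + rng.integers(100, 3000)))
                    for s in starts
                ]
                tracks.append(_track(cl, mk, rows))
        cands, _ = overlap_regulatory(probes, tracks)
        for cand in cands:
            for cl in ("CL1", "CL2"):
                expected = 0
                for t in tracks:
                    if t.cell_line != cl:
                        continue
                    hit = (
                        (t.intervals["chrom"] == cand.chrom)
                        & (t.intervals["start"] <= cand.pos)
                        & (cand.pos < t.intervals["end"])
                    ).any()
                    expected += int(hit)
                assert cand.markers_per_cell_line[cl] == expected

    def test_planted_enhancers_are_stringent(self, truth, manifest, tracks):
        probes = manifest.loc[sorted(truth.enhancer_probes), ["chrom", "pos"]]
        cands, summary = overlap_regulatory(probes, tracks)
        assert all(c.stringent for c in cands)
        assert summary["n_stringent"] == len(truth.enhancer_probes)

    def test_no_tracks_rejected(self):
        probes = pd.DataFrame({"chrom": ["chr1"], "pos": [1]}, index=["p1"])
        with pytest.raises(ValueError):
            overlap_regulatory(probes, [])


class TestFormatPct:
    @pytest.mark.parametrize("k,n,expected", [(113, 260, 43.5), (20, 56, 35.7), (31, 40, 77.5)])
    def test_reported_fractions(self, k, n, expected):
        assert format_pct(k, n) == expected

    def test_half_up(self):
        assert format_pct(1, 8, decimals=0) == 13.0  # 12.5 rounds up


def _cand(probe_id, chrom="chr1", pos=1_000_000, stringent=True):
    return EnhancerCandidate(
        probe_id=probe_id, chrom=chrom, pos=pos,
        markers_per_cell_line={"CL1": 4}, active=True, stringent=stringent,
    )


class TestLinkTargets:
    GENES = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr1"], "tss": [900_000, 1_999_999, 2_500_001]},
        index=["gNear", "gEdge", "gFar"],
    )

    def _de(self, fcs):
        return pd.DataFrame({"log2fc": pd.Series(fcs)})

    def test_window_and_inclusive_gate(self):
        de = self._de({"gNear": 0.2, "gEdge": -3.0, "gFar": 5.0})
        links = link_targets([_cand("p1")], self.GENES, de)
        # gFar is 1.5 Mb away -> excluded; gNear passes at exactly 0.2
        assert set(links["gene_id"]) == {"gNear", "gEdge"}

    def test_subthreshold_gene_excluded(self):
        de = self._de({"gNear": 0.1, "gEdge": 0.19, "gFar": 3.0})
        links = link_targets([_cand("p1")], self.GENES, de)
        assert links["gene_id"].isna().all()  # probe reported with empty link

    def test_nonstringent_candidates_ignored(self):
        de = self._de({"gNear": 1.0})
        links = link_targets([_cand("p1", stringent=False)], self.GENES, de)
        assert len(links) == 0

    def test_gene_order_invariance(self):
        de = self._de({"gNear": 1.0, "gEdge": -1.0, "gFar": 1.0})
        fwd = link_targets([_cand("p1")], self.GENES, de)
        rev = link_targets([_cand("p1")], self.GENES.iloc[::-1], de)
        assert sorted(fwd["gene_id"]) == sorted(rev["gene_id"])


class TestClassifyDependency:
    def _tables(self, d_hyp, d_hif, q_hif, l_hif):
        links = pd.DataFrame(
            {"probe_id": ["p1"], "gene_id": ["g1"], "distance": [1000],
             "log2fc_hypoxia": [-0.5]}
        )
        dm_hyp = pd.DataFrame({"delta_beta": [d_hyp], "q_value": [0.01]}, index=["p1"])
        dm_hif = pd.DataFrame({"delta_beta": [d_hif], "q_value": [q_hif]}, index=["p1"])
        de_hif = pd.DataFrame({"log2fc": [l_hif]}, index=["g1"])
        return links, dm_hyp, dm_hif, de_hif

    def test_fully_inverted_is_dependent(self):
        links, *rest = self._tables(0.3, -0.25, 0.01, 0.4)
        out = classify_dependency(links, *rest)
        assert out.at[0, "dependency"] == "hif1a_dependent"

    def test_not_significant_is_independent(self):
        links, *rest = self._tables(0.3, 0.01, 0.9, 0.05)
        out = classify_dependency(links, *rest)
        assert out.at[0, "dependency"] == "hif1a_independent"

    def test_mixed_pattern_is_ambiguous(self):
        # probe inverts but target does not respond in the HIF1A contrast
        links, *rest = self._tables(0.3, -0.25, 0.01, 0.05)
        out = classify_dependency(links, *rest)
        assert out.at[0, "dependency"] == "ambiguous"

    def test_planted_split_recovered_exactly(self, truth, bundle):
        """The 9 independent / 5 dependent planted enhancer probes come back."""
        dep = bundle["probe_dependency"]
        counts = dep.value_counts()
        assert counts.get("hif1a_independent", 0) == 9
        assert counts.get("hif1a_dependent", 0) == 5
        for probe, expected in truth.enhancer_dependency.items():
            assert dep[probe] == f"hif1a_{expected}"

    def test_probe_summary_prefers_informative_label(self):
        table = pd.DataFrame(
            {"probe_id": ["p1", "p1"], "dependency": ["ambiguous", "hif1a_dependent"]}
        )
        assert summarize_probe_dependency(table)["p1"] == "hif1a_dependent"
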