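from types import SimpleNamespace

import numpy as np
import pytest

import psphunter as psp
from psphunter.scan import (ResidueScoreTrack, apply_mutation, parse_mutation,
                            scan_centers, window_for_center)


class TestTruncationVariants:
    def test_enumeration_at_L60(self):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(60))
        variants = psp.truncation_variants(seq)
        assert len(variants) == 40
        assert [c for c, _ in variants] == list(range(11, 51))
        assert all(len(v) == 40 for _, v in variants)

    def test_boundary_L21(self):
        seq = "A" * 10 + "W" + "A" * 10
        variants = psp.truncation_variants(seq)
        assert len(variants) == 1
        center, var = variants[0]
        assert center == 11 and len(var) == 1

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 75))
        for center, var in psp.truncation_variants(seq):
            start, end = window_for_center(center)
            assert var == seq[:start - 1] + seq[end:]
            assert seq[start - 1:end] not in ("",)
            assert len(seq) - len(var) == 20

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            psp.truncation_variants("A" * 20)

    def test_margin_shifts_with_length(self):
        # prepending residues shifts the defined window, structure intact
        for L in (60, 70):
            centers = scan_centers(L)
            assert centers[0] == 11 and centers[-1] == L - 10
            assert len(centers) == L - 20


def _constant_model(score=0.6, n_features=122):
    forest = SimpleNamespace(
        predict_proba=lambda X: np.tile([1 - score, score], (len(X), 1)),
        classes_=np.array([0, 1]),
        n_features_in_=n_features,
        n_estimators=1)
    return psp.TrainedModel(forest=forest)


class TestScanTrack:
    def test_flat_profile_gives_zero_deltas(self, bundle, extractor):
        rec = bundle.positives[0]
        track = psp.scan_track(_constant_model(), extractor, rec)
        np.testing.assert_allclose(track.deltas, 0.0, atol=1e-15)

    def test_defined_positions_contract(self, bundle, extractor, model):
        rec = bundle.positives[0]
        track = psp.scan_track(model, extractor, rec)
        assert len(track.centers) == rec.length - 20
        assert track.centers[0] == 11 and track.centers[-1] == rec.length - 10
        assert not track.is_defined(10)
        assert not track.is_defined(rec.length - 9)
        with pytest.raises(KeyError):
            track.delta_at(1)

    def test_matches_independent_per_variant_rescoring(self, bundle,
                                                       extractor, model):
        """Oracle: assemble each truncated variant's feature vector by hand
        from the individual block functions (annotation and network frozen
        at the wild type) and rescore it, bypassing the extractor."""
        import networkx as nx

        from psphunter import (annotation_block, composition_block,
                               embed_sequence, network_block)
        from psphunter.features import funcsite_block

        rec = next(r for r in bundle.positives if r.length < 260)
        track = psp.scan_track(model, extractor, rec)
        tracks = bundle.tracks[rec.id]
        betweenness = nx.betweenness_centrality(bundle.graph,
                                                normalized=False)
        ann, _ = annotation_block(rec.id, rec.length, bundle.tables)
        net = network_block(rec.id, bundle.graph, betweenness)
        for idx in range(0, len(track.centers), 7):
            center = int(track.centers[idx])
            start, end = window_for_center(center)
            keep = np.r_[0:start - 1, end:rec.length]
            var_seq = rec.sequence[:start - 1] + rec.sequence[end:]
            sub = tracks.subset(keep)
            fs = funcsite_block(psp.ProteinRecord(rec.id, "A" * sub.length),
                                sub)
            fs[-1] = len(var_seq)
            vec = np.concatenate([
                composition_block(var_seq), np.zeros(4), np.zeros(5),
                np.zeros(4), fs, embed_sequence(var_seq, extractor.embedding),
                ann, net,
            ])
            oracle_score = psp.predict_scores(model, vec)[0]
            expected_delta = track.mean_variant_score - oracle_score
            assert track.deltas[idx] == pytest.approx(expected_delta,
                                                      abs=1e-12)

    def test_full_reference_switch(self, bundle, extractor, model):
        rec = bundle.positives[1]
        track = psp.scan_track(model, extractor, rec, reference="full")
        np.testing.assert_allclose(
            track.deltas, track.full_score - track.variant_scores)


class TestCandidateSelection:
    def _track(self, L, deltas=None, seed=0):
        centers = np.arange(11, L - 9)
        if deltas is None:
            deltas = np.random.default_rng(seed).random(len(centers))
        # variant_scores chosen so that mean - score == requested delta
        scores = -np.asarray(deltas, dtype=float)
        scores = scores - scores.mean()
        return ResidueScoreTrack("p", L, centers, scores, full_score=0.9)

    def test_five_percent_band_at_400(self):
        assert len(psp.select_candidates(self._track(400))) == 20

    def test_one_percent_band_at_2500(self):
        assert len(psp.select_candidates(self._track(2500))) == 25

    @pytest.mark.parametrize("L,expected", [
        (500, 25), (501, 20), (1000, 40), (1001, 20), (2000, 40), (2001, 20),
    ])
    def test_band_boundaries(self, L, expected):
        assert len(psp.select_candidates(self._track(L))) == expected

    def test_tie_breaks_toward_smaller_position(self):
        L = 400
        deltas = np.zeros(L - 20)
        centers = np.arange(11, L - 9)
        deltas[np.flatnonzero(centers == 40)[0]] = 1.0
        deltas[np.flatnonzero(centers == 80)[0]] = 1.0
        track = self._track(L, deltas)
        top = psp.select_candidates(track, n_candidates=1)
        assert top == [40]

    def test_rounding_to_zero_keeps_one(self):
        track = self._track(30)  # 5% of 30 rounds to 2; force via n=0 path
        assert len(psp.select_candidates(self._track(9 + 21))) >= 1
        assert psp.select_candidates(track, n_candidates=0)  # warns, keeps 1

    def test_absolute_count_mode(self):
        track = self._track(800)
        assert len(psp.select_candidates(track, n_candidates=30)) == 30


class TestMergeRegions:
    def _track_for(self, positions_delta):
        L = 400
        centers = np.arange(11, L - 9)
        deltas = np.zeros(len(centers))
        for pos, d in positions_delta.items():
            deltas[np.flatnonzero(centers == pos)[0]] = d
        scores = -(deltas - deltas.mean())
        return ResidueScoreTrack("p", L, centers, scores, full_score=0.5)

    def test_adjacency(self):
        track = self._track_for({p: 1.0 for p in range(100, 111)} | {200: 2.0})
        regions = psp.merge_regions(list(range(100, 111)) + [200], track)
        assert [(r.start, r.end) for r in regions] == [(100, 110), (200, 200)]
        assert regions[1].rank == 1  # higher mean delta

    def test_gap_tolerance(self):
        track = self._track_for({30: 1.0, 32: 1.0})
        regions = psp.merge_regions([30, 32], track, gap=1)
        assert [(r.start, r.end) for r in regions] == [(30, 32)]

    def test_region_count_bounded_by_candidates(self):
        track = self._track_for({30: 1.0, 50: 1.0, 70: 1.0})
        regions = psp.merge_regions([30, 50, 70], track)
        assert len(regions) <= 3

    def test_empty_candidates_rejected(self):
        track = self._track_for({30: 1.0})
        with pytest.raises(ValueError, match="empty"):
            psp.merge_regions([], track)


class TestKeyBlockRecovery:
    def test_planted_block_recovered(self, bundle, extractor, model):
        """On most fixture positives, at least half of the selected
        candidates must fall inside the planted sticky block, and the
        strongest delta must point at it."""
        hits = argmax_hits = n = 0
        for rec in bundle.positives[:12]:
            track = psp.scan_track(model, extractor, rec)
            start, end = bundle.key_blocks[rec.id]
            candidates = psp.select_candidates(track)
            frac = np.mean([start <= c <= end for c in candidates])
            hits += frac >= 0.5
            peak = int(track.centers[np.argmax(track.deltas)])
            argmax_hits += start <= peak <= end
            n += 1
        assert hits / n >= 0.8
        assert argmax_hits / n >= 0.8


class TestMutations:
    def test_parse_notation(self):
        sub = parse_mutation("G100V")
        assert (sub.kind, sub.start, sub.ref, sub.alt) == \
            ("substitution", 100, "G", "V")
        dele = parse_mutation("A322-E327del")
        assert (dele.kind, dele.start, dele.end) == ("deletion", 322, 327)
        fus = parse_mutation("fuse:GYGPGS")
        assert (fus.kind, fus.tag) == ("idr_fusion", "GYGPGS")
        with pytest.raises(ValueError, match="parse"):
            parse_mutation("nonsense")

    def test_identity_substitution_zero_impact(self, bundle, extractor, model):
        rec = bundle.positives[0]
        mut = psp.MutationSpec("substitution", start=50, end=50,
                               ref=rec.sequence[49], alt=rec.sequence[49])
        assert psp.mutation_impact(model, extractor, rec, mut) == 0.0

    def test_ref_mismatch_cites_position(self, bundle):
        rec = bundle.positives[0]
        wrong = "A" if rec.sequence[9] != "A" else "C"
        with pytest.raises(ValueError, match="position 10"):
            apply_mutation(rec.sequence,
                           psp.MutationSpec("substitution", start=10, end=10,
                                            ref=wrong, alt="G"))

    def test_deletion_interval_bounds(self):
        with pytest.raises(ValueError, match="outside"):
            apply_mutation("ACDEF", psp.MutationSpec("deletion", start=3,
                                                     end=9))

    def test_key_block_deletion_beats_control(self, bundle, extractor, model):
        """Deleting the planted block must cost more predicted capacity than
        deleting an equal-length block elsewhere, for most positives."""
        wins = n = 0
        for rec in bundle.positives[:8]:
            start, end = bundle.key_blocks[rec.id]
            key = psp.MutationSpec("deletion", start=start, end=end,
                                   ref=rec.sequence[start - 1],
                                   alt=rec.sequence[end - 1])
            ctrl_start = 5 if start > 60 else end + 10
            ctrl_end = ctrl_start + (end - start)
            if ctrl_end >= rec.length:
                continue
            ctrl = psp.MutationSpec("deletion", start=ctrl_start,
                                    end=ctrl_end,
                                    ref=rec.sequence[ctrl_start - 1],
                                    alt=rec.sequence[ctrl_end - 1])
            n += 1
            wins += (psp.mutation_impact(model, extractor, rec, key)
                     > psp.mutation_impact(model, extractor, rec, ctrl))
        assert n >= 5 and wins / n >= 0.8

    def test_sticky_tag_fusion_rescues_deleted_form(self, bundle, extractor,
                                                    model):
        """Fusing a GP/aromatic-rich tag back onto the block-deleted form
        must raise the score above the deleted form for most positives."""
        tag = "".join(v + "GP" for v in bundle.sticky_vocab)
        wins = n = 0
        for rec in bundle.positives[:8]:
            start, end = bundle.key_blocks[rec.id]
            del_seq, keep = apply_mutation(
                rec.sequence, psp.MutationSpec("deletion", start=start,
                                               end=end))
            s_del = psp.predict_scores(
                model, extractor.variant_vector(rec, del_seq, keep))[0]
            s_rescue = psp.predict_scores(
                model, extractor.variant_vector(rec, del_seq + tag, keep))[0]
            n += 1
            wins += s_rescue > s_del
        assert wins / n >= 0.8
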