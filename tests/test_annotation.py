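"""Annotation sessions: edits, event sourcing, timing arithmetic, speed-up."""

import numpy as np
import pytest

from ctlabel.annotation import (
    AnnotationSession,
    EditEvent,
    NoDataError,
    SessionIndexError,
    SessionParseError,
    SessionSummary,
    apply_edit,
    compare_sessions,
    export_session,
    final_masks,
    import_session,
    propose,
    round_half_away,
    session_summary,
    speedup_report,
)
from ctlabel.model import ModelSpec, build_model


def blob(r0, r1, c0, c1, size=16):
    m = np.zeros((size, size), bool)
    m[r0:r1, c0:c1] = True
    return m


def make_session(n_scans=1, n_slices=4, with_proposals=True):
    session = AnnotationSession()
    proposal = blob(4, 8, 4, 8)
    for k in range(n_scans):
        proposals = [proposal.copy() for _ in range(n_slices)] if with_proposals else None
        session.register_scan(f"scan{k}", n_slices, proposals=proposals)
    return session


class TestPropose:
    def test_one_proposal_per_slice_no_events(self):
        model = build_model(ModelSpec(width_multiplier=0.0625, encoder_depth=18), 0)
        session = AnnotationSession()
        slices = [np.zeros((64, 64), np.uint16)] * 5
        masks = propose(session, "s0", slices, model)
        assert len(masks) == 5
        scan = session.scans["s0"]
        assert scan.events == [] and scan.slice_count == 5

    def test_biased_model_proposes_empty(self):
        model = build_model(ModelSpec(width_multiplier=0.0625, encoder_depth=18), 0)
        model.decoder.head.bias.data -= 10.0  # output probability ~0
        session = AnnotationSession()
        masks = propose(session, "s0", [np.zeros((64, 64), np.uint16)] * 3, model)
        assert all(not m.any() for m in masks)

    def test_overfit_model_overlaps_ground_truth(self, phantom_dataset):
        """A model trained briefly on a phantom proposes masks that overlap
        the generator's ground truth."""
        from ctlabel.dicom_io import manifest_slice_arrays
        from ctlabel.evaluation import confusion_counts, dsc
        from ctlabel.training import (TrainConfig, filter_empty_slices,
                                      merge_datasets, train)

        _, manifests = phantom_dataset
        records = filter_empty_slices(merge_datasets(manifests))[:16]
        model = build_model(ModelSpec(width_multiplier=0.125, encoder_depth=18), 1)
        cfg = TrainConfig(epochs=8, batch_size=4, lr0=1e-3, milestones=(), seed=1)
        model, _ = train(model, records, cfg)

        session = AnnotationSession()
        data = list(manifest_slice_arrays(manifests[0]))
        organ = [(img, mask) for _, img, mask in data if mask.any()]
        masks = propose(session, "p0", [img for img, _ in organ], model)
        total = None
        for pred, (_, gt) in zip(masks, organ):
            c = confusion_counts(pred, gt)
            total = c if total is None else total + c
        assert dsc(total) > 0


class TestApplyEdit:
    def test_accept_copies_proposal(self):
        session = make_session()
        apply_edit(session, EditEvent("scan0", 0, "accept", 3.0))
        scan = session.scans["scan0"]
        np.testing.assert_array_equal(scan.finals[0], scan.proposals[0])
        assert scan.status[0] == "accepted"

    def test_replace_overrides_proposal(self):
        session = make_session()
        new = blob(0, 2, 0, 2)
        apply_edit(session, EditEvent("scan0", 1, "replace", 5.0, payload=new))
        np.testing.assert_array_equal(session.scans["scan0"].finals[1], new)

    def test_add_then_erase_is_identity_on_empty(self):
        session = AnnotationSession()
        session.register_scan("s", 1, proposals=[blob(0, 0, 0, 0)])
        region = blob(2, 6, 2, 6)
        apply_edit(session, EditEvent("s", 0, "add_region", 1.0, payload=region))
        apply_edit(session, EditEvent("s", 0, "erase_region", 1.0, payload=region))
        assert not session.scans["s"].finals[0].any()

    def test_create_on_unproposed_slice(self):
        session = make_session(with_proposals=False)
        new = blob(1, 3, 1, 3)
        apply_edit(session, EditEvent("scan0", 2, "create", 9.0, payload=new))
        np.testing.assert_array_equal(session.scans["scan0"].finals[2], new)

    def test_erase_on_empty_warns_noop(self):
        session = AnnotationSession()
        session.register_scan("s", 1, proposals=[blob(0, 0, 0, 0)])
        with pytest.warns(UserWarning):
            apply_edit(session, EditEvent("s", 0, "erase_region", 1.0,
                                          payload=blob(1, 2, 1, 2)))
        assert not session.scans["s"].finals[0].any()

    def test_unknown_slice_rejected(self):
        session = make_session()
        with pytest.raises(SessionIndexError):
            apply_edit(session, EditEvent("scan0", 99, "accept", 1.0))
        with pytest.raises(SessionIndexError):
            apply_edit(session, EditEvent("ghost", 0, "accept", 1.0))

    def test_event_validation(self):
        with pytest.raises(ValueError):
            EditEvent("s", 0, "accept", -1.0)
        with pytest.raises(ValueError):
            EditEvent("s", 0, "replace", 1.0)  # payload required
        with pytest.raises(ValueError):
            EditEvent("s", 0, "flub", 1.0)


class TestSessionSummary:
    def test_table_style_worked_examples(self):
        """Printed-totals arithmetic: assisted/manual throughput on two
        datasets reproduces the reported per-slice and per-scan figures."""
        external_assisted = SessionSummary(32, 3223.0, 1313)
        external_manual = SessionSummary(32, 8486.0, 926)
        second_assisted = SessionSummary(39, 10304.0, 2402)
        second_manual = SessionSummary(31, 12287.0, 884)

        assert external_assisted.rounded()["time_per_slice_s"] == 2.5
        assert external_manual.rounded()["time_per_slice_s"] == 9.2
        assert second_assisted.rounded()["time_per_slice_s"] == 4.3
        assert second_manual.rounded()["time_per_slice_s"] == 13.9
        assert second_assisted.rounded()["avg_time_per_scan_s"] == 264.2
        assert second_assisted.rounded()["avg_slices_per_scan"] == 61.6

    def test_single_event_session(self):
        session = make_session(n_scans=1, n_slices=1)
        apply_edit(session, EditEvent("scan0", 0, "accept", 7.0))
        summary = session_summary(session)
        assert summary.time_per_slice_s == 7.0
        assert summary.total_time_s == 7.0

    def test_ratios_consistent_with_totals(self):
        session = make_session(n_scans=2, n_slices=3)
        for k in range(2):
            for i in range(3):
                apply_edit(session, EditEvent(f"scan{k}", i, "accept", 2.0 + i))
        s = session_summary(session)
        assert s.time_per_slice_s == pytest.approx(s.total_time_s / s.total_slices)
        assert s.avg_time_per_scan_s == pytest.approx(s.total_time_s / s.n_scans)
        assert s.avg_slices_per_scan == pytest.approx(s.total_slices / s.n_scans)
        # per-scan elapsed sums to the total
        assert sum(sc.elapsed for sc in session.scans.values()) == s.total_time_s

    def test_fraction_unmodified_extremes(self):
        session = make_session(n_scans=1, n_slices=3)
        for i in range(3):
            apply_edit(session, EditEvent("scan0", i, "accept", 1.0))
        assert session_summary(session).fraction_unmodified == 1.0

        session2 = make_session(n_scans=1, n_slices=3)
        for i in range(3):
            apply_edit(session2, EditEvent("scan0", i, "replace", 1.0,
                                           payload=blob(0, 2, 0, 2)))
        assert session_summary(session2).fraction_unmodified == 0.0

    def test_accept_then_edit_counts_as_modified(self):
        session = make_session(n_scans=1, n_slices=2)
        apply_edit(session, EditEvent("scan0", 0, "accept", 1.0))
        apply_edit(session, EditEvent("scan0", 1, "accept", 1.0))
        apply_edit(session, EditEvent("scan0", 1, "add_region", 2.0,
                                      payload=blob(0, 2, 0, 2)))
        assert session_summary(session).fraction_unmodified == 0.5

    def test_empty_session_rejected(self):
        with pytest.raises(NoDataError):
            session_summary(AnnotationSession())

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(2.45) == 2.5
        assert round_half_away(-2.45) == -2.5
        assert round_half_away(2.44) == 2.4


class TestCompareSessions:
    def test_external_dataset_ratio(self):
        cmp = compare_sessions(SessionSummary(32, 3223.0, 1313),
                               SessionSummary(32, 8486.0, 926))
        assert round_half_away(cmp["speedup_per_slice"], 2) == 3.73
        # ratio of the rounded printed values
        assert 9.2 / 2.5 == pytest.approx(3.68)

    def test_identical_summaries_unity(self):
        s = SessionSummary(2, 100.0, 50)
        assert compare_sessions(s, s)["speedup_per_slice"] == 1.0

    def test_pooled_and_mean_aggregations_both_reported(self):
        pairs = [
            (SessionSummary(32, 3223.0, 1313), SessionSummary(32, 8486.0, 926)),
            (SessionSummary(39, 10304.0, 2402), SessionSummary(31, 12287.0, 884)),
        ]
        report = speedup_report(pairs)
        assert report["total_assisted_slices"] == 3715
        assert report["pooled_speedup"] == pytest.approx(3.15, abs=0.01)
        # from exact totals (the printed one-decimal values would give 3.46)
        assert report["mean_of_per_dataset"] == pytest.approx(3.49, abs=0.01)

    def test_zero_assisted_time_rejected(self):
        with pytest.raises(ZeroDivisionError):
            compare_sessions(SessionSummary(1, 0.0, 10), SessionSummary(1, 5.0, 10))


class TestSessionRoundTrip:
    def _random_session(self, seed):
        rng = np.random.default_rng(seed)
        session = AnnotationSession()
        n_scans = int(rng.integers(1, 4))
        for k in range(n_scans):
            n = int(rng.integers(1, 6))
            proposals = [
                (rng.random((16, 16)) > 0.7) if rng.random() > 0.3 else None
                for _ in range(n)
            ]
            session.register_scan(f"s{k}", n, proposals=proposals)
            for i in range(n):
                if session.scans[f"s{k}"].proposals[i] is None:
                    apply_edit(session, EditEvent(
                        f"s{k}", i, "create", float(rng.integers(1, 20)),
                        payload=rng.random((16, 16)) > 0.6))
                    continue
                action = rng.choice(["accept", "replace", "add_region"])
                payload = (rng.random((16, 16)) > 0.6) if action != "accept" else None
                apply_edit(session, EditEvent(
                    f"s{k}", i, str(action), float(rng.integers(1, 20)),
                    payload=payload))
        return session

    def test_export_import_equal_summaries(self, tmp_path):
        session = self._random_session(0)
        export_session(session, tmp_path / "log.json")
        back = import_session(tmp_path / "log.json")
        assert session_summary(back) == session_summary(session)

    def test_replay_reproduces_final_masks_bit_exactly(self, tmp_path):
        for seed in range(10):
            session = self._random_session(seed)
            path = tmp_path / f"log{seed}.json"
            export_session(session, path)
            back = import_session(path)
            for sid in session.scans:
                for a, b in zip(final_masks(session, sid), final_masks(back, sid)):
                    if a is None:
                        assert b is None
                    else:
                        np.testing.assert_array_equal(a, b)

    def test_negative_elapsed_rejected_on_import(self, tmp_path):
        session = make_session(n_scans=1, n_slices=1)
        apply_edit(session, EditEvent("scan0", 0, "accept", 2.0))
        path = tmp_path / "log.json"
        export_session(session, path)
        text = path.read_text().replace('"elapsed": 2.0', '"elapsed": -2.0')
        path.write_text(text)
        with pytest.raises(SessionParseError):
            import_session(path)

    def test_malformed_json_reports_line(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json\n")
        with pytest.raises(SessionParseError, match="line"):
            import_session(tmp_path / "bad.json")
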