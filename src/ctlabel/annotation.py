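"""Headless model-assisted annotation sessions with timing accounting.

A session mirrors how a reviewer works through CT scans with model
assistance: the segmentation model proposes a mask for every slice, the
reviewer then accepts each proposal as-is, replaces it, edits it by adding
or erasing regions, or creates a mask from scratch on a slice with no
proposal. Every action is an :class:`EditEvent` carrying its elapsed time,
supplied by the caller (from logs or an external clock), never measured
internally — so summaries are deterministic and replayable.

The event log is authoritative: replaying it against the stored proposals
reproduces the final masks bit-exactly (event sourcing). Summaries report
total and per-slice/per-scan times plus the fraction of reviewed slices
accepted without revision; all ratio fields are derived from the totals, and
printed ratios are rounded to one decimal, half away from zero. Speed-up
between an assisted and a manual session is the ratio of their per-slice
times; across several datasets both the pooled ratio and the mean of
per-dataset ratios are reported, since the two aggregations genuinely
differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .dicom_io import MaskImage
from .model import SegmentationModel, predict_mask


class NoDataError(ValueError):
    pass


class SessionIndexError(IndexError):
    pass


class SessionParseError(ValueError):
    pass


class UndefinedRatioError(ZeroDivisionError):
    pass


VALID_ACTIONS = ("accept", "replace", "add_region", "erase_region", "create")


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals."""
    factor = 10.0**decimals
    scaled = value * factor
    return (np.floor(scaled + 0.5) if scaled >= 0 else np.ceil(scaled - 0.5)) / factor


@dataclass
class EditEvent:
    """One reviewer action on one slice."""

    scan_id: str
    slice_index: int
    action: str
    elapsed: float  # seconds
    payload: Optional[np.ndarray] = None  # mask for replace/create/region ops

    def __post_init__(self):
        if self.action not in VALID_ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if self.elapsed < 0:
            raise ValueError("elapsed time must be non-negative")
        if self.payload is not None:
            self.payload = np.asarray(
                getattr(self.payload, "pixels", self.payload), dtype=bool
            )
        elif self.action in ("replace", "create", "add_region", "erase_region"):
            raise ValueError(f"action {self.action!r} requires a mask payload")


@dataclass
class _ScanState:
    slice_count: int
    proposals: List[Optional[np.ndarray]]
    finals: List[Optional[np.ndarray]]
    status: List[str]  # "proposed" | "accepted" | "edited" | "created"
    events: List[EditEvent] = field(default_factory=list)

    @property
    def elapsed(self) -> float:
        return sum(e.elapsed for e in self.events)


class AnnotationSession:
    """Per-scan log of proposals, reviewer events and elapsed times."""

    def __init__(self, tool_tag: str = "assisted"):
        self.tool_tag = tool_tag
        self.scans: Dict[str, _ScanState] = {}

    def register_scan(self, scan_id: str, slice_count: int,
                      proposals: Optional[Sequence[Optional[np.ndarray]]] = None):
        if proposals is None:
            proposals = [None] * slice_count
        proposals = [None if p is None
                     else np.asarray(getattr(p, "pixels", p), dtype=bool)
                     for p in proposals]
        if len(proposals) != slice_count:
            raise ValueError("proposal count does not match slice count")
        self.scans[scan_id] = _ScanState(
            slice_count=slice_count,
            proposals=proposals,
            finals=[None if p is None else p.copy() for p in proposals],
            status=["proposed"] * slice_count,
        )

    @property
    def total_time_s(self) -> float:
        return sum(s.elapsed for s in self.scans.values())

    @property
    def total_slices(self) -> int:
        return sum(s.slice_count for s in self.scans.values())


def propose(session: AnnotationSession, scan_id: str,
            slices: Sequence[np.ndarray], model: SegmentationModel,
            threshold: float = 0.5, y_max: int = 65535) -> List[np.ndarray]:
    """Attach model proposals for a scan's slices to the session."""
    masks = predict_mask(model, slices, threshold=threshold, y_max=y_max)
    session.register_scan(scan_id, len(masks), proposals=masks)
    return masks


def apply_edit(session: AnnotationSession, event: EditEvent) -> AnnotationSession:
    """Apply one reviewer event to the session state and append it to the log.

    accept: final mask = proposal, slice flagged unmodified.
    replace: final mask = payload.
    add_region / erase_region: set union / difference with the payload.
    create: final mask on a slice with no proposal.
    Erasing from an empty mask is a recorded no-op.
    """
    if event.scan_id not in session.scans:
        raise SessionIndexError(f"unknown scan {event.scan_id!r}")
    scan = session.scans[event.scan_id]
    i = event.slice_index
    if not 0 <= i < scan.slice_count:
        raise SessionIndexError(f"slice {i} out of range for {event.scan_id!r}")

    current = scan.finals[i]
    if event.action == "accept":
        if scan.proposals[i] is None:
            raise ValueError("cannot accept a slice with no proposal")
        scan.finals[i] = scan.proposals[i].copy()
        scan.status[i] = "accepted"
    elif event.action == "replace":
        scan.finals[i] = event.payload.copy()
        scan.status[i] = "edited"
    elif event.action == "create":
        scan.finals[i] = event.payload.copy()
        scan.status[i] = "created"
    elif event.action == "add_region":
        base = current if current is not None else np.zeros_like(event.payload)
        scan.finals[i] = base | event.payload
        scan.status[i] = "edited"
    elif event.action == "erase_region":
        if current is None or not current.any():
            import warnings

            warnings.warn(f"erase on empty mask ({event.scan_id}[{i}]): no-op")
            scan.finals[i] = (current if current is not None
                              else np.zeros_like(event.payload))
        else:
            scan.finals[i] = current & ~event.payload
        scan.status[i] = "edited"
    scan.events.append(event)
    return session


@dataclass(frozen=True)
class SessionSummary:
    """Throughput aggregates for one session (or one dataset's totals)."""

    n_scans: int
    total_time_s: float
    total_slices: int
    fraction_unmodified: Optional[float] = None

    def __post_init__(self):
        if self.total_slices < 1:
            raise NoDataError("summary needs at least one slice")
        if self.n_scans < 1:
            raise NoDataError("summary needs at least one scan")
        if self.fraction_unmodified is not None and not (
            0.0 <= self.fraction_unmodified <= 1.0
        ):
            raise ValueError("fraction_unmodified must be in [0, 1]")

    # ratio fields are always derived from the totals, never stored
    @property
    def time_per_slice_s(self) -> float:
        return self.total_time_s / self.total_slices

    @property
    def avg_time_per_scan_s(self) -> float:
        return self.total_time_s / self.n_scans

    @property
    def avg_slices_per_scan(self) -> float:
        return self.total_slices / self.n_scans

    def rounded(self, decimals: int = 1) -> dict:
        """Report-style dict with ratios rounded half away from zero."""
        out = {
            "n_scans": self.n_scans,
            "total_time_s": self.total_time_s,
            "total_slices": self.total_slices,
            "time_per_slice_s": round_half_away(self.time_per_slice_s, decimals),
            "avg_time_per_scan_s": round_half_away(self.avg_time_per_scan_s, decimals),
            "avg_slices_per_scan": round_half_away(self.avg_slices_per_scan, decimals),
        }
        if self.fraction_unmodified is not None:
            out["fraction_unmodified"] = round_half_away(
                self.fraction_unmodified, decimals + 1
            )
        return out


def session_summary(session: AnnotationSession) -> SessionSummary:
    """Aggregate a session into totals and derived ratios.

    ``fraction_unmodified`` counts slices whose final state is an accepted
    proposal with no later region edits, over all slices that received at
    least one review event.
    """
    if not session.scans or session.total_slices == 0:
        raise NoDataError("session has no slices")
    reviewed = accepted = 0
    for scan in session.scans.values():
        touched = {e.slice_index for e in scan.events}
        reviewed += len(touched)
        accepted += sum(1 for i in touched if scan.status[i] == "accepted")
    fraction = accepted / reviewed if reviewed else None
    return SessionSummary(
        n_scans=len(session.scans),
        total_time_s=session.total_time_s,
        total_slices=session.total_slices,
        fraction_unmodified=fraction,
    )


def compare_sessions(assisted: SessionSummary, manual: SessionSummary) -> dict:
    """Per-slice speed-up of assisted over manual annotation."""
    if assisted.time_per_slice_s == 0:
        raise UndefinedRatioError("assisted time per slice is zero")
    return {
        "assisted_time_per_slice_s": assisted.time_per_slice_s,
        "manual_time_per_slice_s": manual.time_per_slice_s,
        "speedup_per_slice": manual.time_per_slice_s / assisted.time_per_slice_s,
    }


def speedup_report(pairs: Sequence[tuple]) -> dict:
    """Speed-up across datasets, each given as (assisted, manual) summaries.

    Reports the per-dataset per-slice ratios, their mean, and the pooled
    ratio (totals summed over datasets first). The two aggregations answer
    different questions and generally disagree; both are printed.
    """
    if not pairs:
        raise NoDataError("no dataset pairs")
    per_dataset = [compare_sessions(a, m)["speedup_per_slice"] for a, m in pairs]
    a_time = sum(a.total_time_s for a, _ in pairs)
    a_slices = sum(a.total_slices for a, _ in pairs)
    m_time = sum(m.total_time_s for _, m in pairs)
    m_slices = sum(m.total_slices for _, m in pairs)
    pooled = (m_time / m_slices) / (a_time / a_slices)
    return {
        "per_dataset_speedup": per_dataset,
        "mean_of_per_dataset": float(np.mean(per_dataset)),
        "pooled_speedup": pooled,
        "total_assisted_slices": a_slices,
        "note": "pooled and per-dataset-mean aggregations differ; both reported",
    }


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def _mask_to_rle(mask: Optional[np.ndarray]):
    """Compact row-major run-length encoding for JSON storage."""
    if mask is None:
        return None
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    runs = np.diff(np.concatenate(([0], changes + 1, [flat.size])))
    return {"shape": list(mask.shape), "first": bool(flat[0]) if flat.size else False,
            "runs": runs.tolist()}


def _mask_from_rle(obj) -> Optional[np.ndarray]:
    if obj is None:
        return None
    flat = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
    value, pos = obj["first"], 0
    for run in obj["runs"]:
        flat[pos : pos + run] = value
        pos += run
        value = not value
    return flat.reshape(obj["shape"])


def export_session(session: AnnotationSession, path) -> None:
    """Serialize the session (proposals + event log) losslessly to JSON."""
    payload = {
        "tool_tag": session.tool_tag,
        "scans": [
            {
                "scan_id": sid,
                "slice_count": scan.slice_count,
                "proposals": [_mask_to_rle(p) for p in scan.proposals],
                "events": [
                    {
                        "slice_index": e.slice_index,
                        "action": e.action,
                        "elapsed": e.elapsed,
                        "payload": _mask_to_rle(e.payload),
                    }
                    for e in scan.events
                ],
            }
            for sid, scan in session.scans.items()
        ],
    }
    Path(path).write_text(json.dumps(payload))


def import_session(path) -> AnnotationSession:
    """Rebuild a session by replaying the exported event log."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    session = AnnotationSession(tool_tag=payload.get("tool_tag", "assisted"))
    for scan in payload["scans"]:
        session.register_scan(
            scan["scan_id"], scan["slice_count"],
            proposals=[_mask_from_rle(p) for p in scan["proposals"]],
        )
        for k, ev in enumerate(scan["events"]):
            try:
                event = EditEvent(
                    scan_id=scan["scan_id"],
                    slice_index=ev["slice_index"],
                    action=ev["action"],
                    elapsed=ev["elapsed"],
                    payload=_mask_from_rle(ev.get("payload")),
                )
            except (KeyError, ValueError) as exc:
                raise SessionParseError(
                    f"{path}: scan {scan['scan_id']!r} event {k}: {exc}"
                ) from exc
            apply_edit(session, event)
    return session


def final_masks(session: AnnotationSession, scan_id: str) -> List[Optional[np.ndarray]]:
    if scan_id not in session.scans:
        raise SessionIndexError(f"unknown scan {scan_id!r}")
    return [None if m is None else m.copy() for m in session.scans[scan_id].finals]
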