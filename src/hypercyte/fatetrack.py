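"""Nuclear tracking across time-lapse frames and mitotic-fate classification.

Tracking is greedy nearest-neighbor with a maximum-displacement gate: for
each consecutive frame pair, candidate links are taken in order of
increasing distance.  An unmatched new nucleus appearing within the gate of
an active track's previous position splits that track into daughters
(divisions, including tripolar).  Disappearing tracks end DIED when the
last observation was propidium-iodide-positive, else LOST.

Fates are classified per mitosis entry (a rounding cue — either a
simulator-provided flag or an area-drop + Hoechst-rise heuristic):

* two or more daughters persisting >= 3 frames  → SUCCESSFUL_DIVISION
* death (PI onset / disappearance) in the window → MITOTIC_CATASTROPHE
* transient separation that re-merges into one nucleus at least as large
  as the pre-mitotic nucleus                     → MITOTIC_SLIPPAGE
* anything ambiguous, stalled or lost            → UNCLEAR

Death accounting follows exact integer arithmetic:
total_deaths = n_start + n_divisions − n_end, and the hourly death rate is
expressed as a percentage of the starting nuclei count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

MIN_EVENTS = 5  # outcome breakdowns need >= 5 mitotic events

OUTCOMES = (
    "SUCCESSFUL_DIVISION",
    "MITOTIC_CATASTROPHE",
    "MITOTIC_SLIPPAGE",
    "UNCLEAR",
)


class TrackingError(ValueError):
    pass


@dataclass
class Track:
    track_id: int
    #: ordered (frame, cell_id) observations
    points: list = field(default_factory=list)
    parent_track: int | None = None
    children_tracks: list = field(default_factory=list)
    end_reason: str = "ONGOING"  # ONGOING | DIVIDED | DIED | LOST

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def end_frame(self) -> int:
        return self.points[-1][0]

    @property
    def n_frames(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FateEvent:
    track_id: int
    frame_start: int
    frame_end: int
    outcome: str
    n_daughters: int = 0


def link_tracks(
    frames: list[pd.DataFrame],
    max_link_distance: float = 25.0,
    pi_column: str = "pi_positive",
    max_dna_fold_change: float = 1.4,
) -> list[Track]:
    """Link per-frame nucleus tables into tracks (greedy nearest neighbor).

    Links are taken in ascending distance under ``max_link_distance``; a
    candidate link whose integrated Hoechst changes by more than
    ``max_dna_fold_change`` is vetoed, since a halving/doubling of DNA
    content marks a mitotic product (daughter or re-merged nucleus) rather
    than a continuation.  New nuclei left unlinked become daughters of the
    nearest previous nucleus (division split); disappearing tracks end DIED
    when the last observation was PI-positive, else LOST.
    """
    tracks: list[Track] = []
    active: dict[int, Track] = {}  # cell-slot -> track, keyed by row position

    last_frame_idx = None
    prev = None  # (frame_df, array xy, row->track map)
    for fi, df in enumerate(frames):
        if "frame" in df.columns and len(df):
            f = int(df["frame"].iloc[0])
        else:
            f = fi
        if last_frame_idx is not None and f <= last_frame_idx:
            raise TrackingError("non-monotone frame indices")
        last_frame_idx = f

        xy = df[["centroid_y", "centroid_x"]].to_numpy(float) if len(df) else np.empty((0, 2))
        if prev is None:
            row_track = {}
            for i in range(len(df)):
                t = Track(track_id=len(tracks))
                t.points.append((f, df["cell_id"].iloc[i] if "cell_id" in df else i))
                tracks.append(t)
                row_track[i] = t
            prev = (df, xy, row_track)
            continue

        pdf, pxy, prow_track = prev
        n_prev, n_cur = len(pxy), len(xy)
        matched_prev = np.zeros(n_prev, dtype=bool)
        matched_cur = np.zeros(n_cur, dtype=bool)
        links: dict[int, int] = {}  # cur row -> prev row
        split_parents: dict[int, list[int]] = {}
        d = None
        if n_prev and n_cur:
            d = cdist(pxy, xy)
            dna_p = (
                pdf["integrated_hoechst"].to_numpy(float)
                if "integrated_hoechst" in pdf.columns else None
            )
            dna_c = (
                df["integrated_hoechst"].to_numpy(float)
                if "integrated_hoechst" in df.columns else None
            )
            # greedy ascending-distance links; a link whose DNA content
            # changes more than max_dna_fold_change (e.g. halves into a
            # daughter, or doubles into a re-merged nucleus) is vetoed so
            # mitotic products resolve as lineage, not identity chains
            order = np.argsort(d, axis=None)
            for flat in order:
                i, j = divmod(int(flat), n_cur)
                if d[i, j] > max_link_distance:
                    break
                if matched_prev[i] or matched_cur[j]:
                    continue
                if dna_p is not None and dna_c is not None:
                    a, b = dna_p[i], dna_c[j]
                    if a > 0 and b > 0 and not (
                        1.0 / max_dna_fold_change <= b / a <= max_dna_fold_change
                    ):
                        continue
                matched_prev[i] = matched_cur[j] = True
                links[j] = i

        # an unlinked new nucleus near a previous nucleus is a mitotic
        # product: it becomes a daughter of the nearest previous nucleus
        # (the parent track ends DIVIDED; if the parent also has a greedy
        # continuation, that continuation is reassigned as a sibling)
        for j in range(n_cur):
            if matched_cur[j] or d is None:
                continue
            i = int(np.argmin(d[:, j]))
            if d[i, j] <= max_link_distance:
                split_parents.setdefault(i, []).append(j)
                matched_cur[j] = True

        row_track: dict[int, Track] = {}
        for i, extra in split_parents.items():
            parent = prow_track[i]
            parent.end_reason = "DIVIDED"
            child_rows = list(extra)
            if i in set(links.values()):
                # reassign the continuation as a sibling daughter
                cont = next(j for j, pi_ in links.items() if pi_ == i)
                del links[cont]
                child_rows.append(cont)
            for j in child_rows:
                child = Track(track_id=len(tracks), parent_track=parent.track_id)
                child.points.append((f, df["cell_id"].iloc[j] if "cell_id" in df else j))
                tracks.append(child)
                parent.children_tracks.append(child.track_id)
                row_track[j] = child

        for j, i in links.items():
            t = prow_track[i]
            t.points.append((f, df["cell_id"].iloc[j] if "cell_id" in df else j))
            row_track[j] = t

        # disappearances: DIED if last observation was PI-positive, else LOST
        for i in range(n_prev):
            if matched_prev[i] or i in split_parents:
                continue
            t = prow_track[i]
            if t.end_reason != "ONGOING":
                continue
            pi_pos = bool(pdf[pi_column].iloc[i]) if pi_column in pdf.columns else False
            t.end_reason = "DIED" if pi_pos else "LOST"

        # brand-new nuclei far from everything start fresh tracks
        for j in range(n_cur):
            if j in row_track or matched_cur[j]:
                continue
            t = Track(track_id=len(tracks))
            t.points.append((f, df["cell_id"].iloc[j] if "cell_id" in df else j))
            tracks.append(t)
            row_track[j] = t

        prev = (df, xy, row_track)

    return tracks


def _cell_attr(frame_lookup: dict, frame: int, cell_id, col: str):
    df = frame_lookup.get(frame)
    if df is None:
        return None
    row = df[df["cell_id"] == cell_id]
    if not len(row):
        return None
    return row[col].iloc[0]


def classify_fates(
    tracks: list[Track],
    frames: list[pd.DataFrame],
    *,
    window: int = 6,
    min_daughter_frames: int = 3,
    mitotic_column: str = "mitotic",
) -> list[FateEvent]:
    """Classify one fate per detected mitosis entry.

    Entries come from the ``mitotic`` rounding flag when present, else from
    an area-drop (>20% below the track median) plus mean-Hoechst-rise
    heuristic.
    """
    frame_lookup: dict[int, pd.DataFrame] = {}
    for fi, df in enumerate(frames):
        f = int(df["frame"].iloc[0]) if ("frame" in df.columns and len(df)) else fi
        frame_lookup[f] = df

    by_id = {t.track_id: t for t in tracks}
    events: list[FateEvent] = []

    for t in tracks:
        entry = _mitosis_entry(t, frame_lookup, mitotic_column)
        if entry is None:
            continue
        pre_area = _pre_mitotic_area(t, frame_lookup, entry)
        outcome, n_d, f_end = _resolve_entry(
            t, entry, by_id, frame_lookup, window, min_daughter_frames, pre_area
        )
        events.append(
            FateEvent(track_id=t.track_id, frame_start=entry,
                      frame_end=f_end, outcome=outcome, n_daughters=n_d)
        )
    return events


def _mitosis_entry(t: Track, frame_lookup, mitotic_column):
    have_flag = any(
        mitotic_column in df.columns for df in frame_lookup.values()
    )
    prev_area = None
    for f, cid in t.points:
        if have_flag:
            flag = _cell_attr(frame_lookup, f, cid, mitotic_column)
            if flag:
                return f
        else:
            area = _cell_attr(frame_lookup, f, cid, "area")
            if area is None:
                continue
            if prev_area is not None and area < 0.8 * prev_area:
                hoechst = _cell_attr(frame_lookup, f, cid, "mean_hoechst")
                prev_h = _cell_attr(frame_lookup, t.points[0][0], t.points[0][1],
                                    "mean_hoechst")
                if hoechst is not None and prev_h is not None and hoechst > prev_h:
                    return f
            prev_area = area
    return None


def _pre_mitotic_area(t: Track, frame_lookup, entry):
    pre = [p for p in t.points if p[0] < entry]
    ref = pre[-1] if pre else t.points[0]
    area = _cell_attr(frame_lookup, ref[0], ref[1], "area")
    if area is None:
        return None
    if not pre:
        area = area / 0.75  # entry frame already shows mitotic rounding
    return float(area)


def _daughter_persists(child: Track, min_frames: int) -> bool:
    return child.n_frames >= min_frames or child.end_reason == "DIVIDED"


def _resolve_entry(t, entry, by_id, frame_lookup, window, min_daughter_frames,
                   pre_area):
    deadline = entry + window
    if t.end_reason == "DIVIDED" and t.end_frame <= deadline:
        children = [by_id[c] for c in t.children_tracks]
        slip = _slippage_pattern(children, by_id, frame_lookup, pre_area,
                                 min_daughter_frames)
        if slip is not None:
            return "MITOTIC_SLIPPAGE", 0, slip
        persisting = [c for c in children if _daughter_persists(c, min_daughter_frames)]
        if len(persisting) >= 2:
            return "SUCCESSFUL_DIVISION", len(persisting), t.end_frame
        return "UNCLEAR", 0, t.end_frame
    if t.end_reason == "DIED" and t.end_frame <= deadline:
        return "MITOTIC_CATASTROPHE", 0, t.end_frame
    return "UNCLEAR", 0, min(t.end_frame, deadline)


def _slippage_pattern(children, by_id, frame_lookup, pre_area,
                      min_daughter_frames):
    """Transient separation re-merging into one large nucleus.

    Signature: exactly two daughter lobes, one short-lived (ends LOST when
    the lobes re-merge) while its sibling carries on as a nucleus at least
    as large as the pre-mitotic one.  The post-merge nucleus is either the
    sibling track itself or — when the DNA-doubling veto made the merged
    nucleus a single split-child of the sibling — that lone child.
    """
    if len(children) != 2 or pre_area is None:
        return None
    a, b = children
    for short, sib in ((a, b), (b, a)):
        if short.end_reason != "LOST" or short.n_frames >= min_daughter_frames:
            continue
        merge_frame = short.end_frame + 1
        obs = [p for p in sib.points if p[0] >= merge_frame]
        if not obs and sib.end_reason == "DIVIDED" and len(sib.children_tracks) == 1:
            cont = by_id[sib.children_tracks[0]]
            if abs(cont.start_frame - merge_frame) <= 1:
                obs = cont.points[:1]
        if not obs:
            continue
        area = _cell_attr(frame_lookup, obs[0][0], obs[0][1], "area")
        if area is not None and area >= 0.9 * pre_area:
            return obs[0][0]
    return None


# ---------------------------------------------------------------------------
# death accounting and rates

def death_accounting(
    n_start: int, n_divisions: int, n_end: int, duration_h: float
) -> dict:
    """total_deaths = n_start + n_divisions − n_end (exact integer
    arithmetic); death rate = 100 × (deaths / duration) / n_start  [%/h]."""
    if min(n_start, n_divisions, n_end) < 0:
        raise ValueError("counts must be >= 0")
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if n_start == 0:
        raise ValueError("death rate undefined for n_start = 0")
    total = n_start + n_divisions - n_end
    if total < 0:
        raise ValueError(
            f"inconsistent counts: start {n_start} + divisions {n_divisions} "
            f"< end {n_end}"
        )
    rate = 100.0 * (total / duration_h) / n_start
    return {"total_deaths": int(total), "death_rate_pct_per_hour": float(rate)}


def event_rates(
    events: list[FateEvent],
    n_start: int,
    duration_h: float,
    reference_frequency: float | None = None,
    min_events: int = MIN_EVENTS,
) -> dict:
    """Mitotic frequency and outcome breakdown for one movie/condition.

    ``frequency`` is mitoses per starting cell per hour; when a reference
    (control day-1) frequency is given, ``normalized_frequency`` divides by
    it.  Outcome percentages (summing to 100) are suppressed below
    ``min_events`` mitotic events.
    """
    if n_start <= 0 or duration_h <= 0:
        raise ValueError("n_start and duration must be > 0")
    n_events = len(events)
    freq = n_events / n_start / duration_h
    out: dict = {"n_events": n_events, "frequency_per_cell_per_hour": freq}
    if reference_frequency is not None:
        if reference_frequency <= 0:
            raise ValueError("reference frequency must be > 0")
        out["normalized_frequency"] = freq / reference_frequency
    if n_events >= min_events:
        pct = {}
        for o in OUTCOMES:
            pct[o] = 100.0 * sum(e.outcome == o for e in events) / n_events
        out["outcome_pct"] = pct
    else:
        out["outcome_pct"] = None
    return out


def catastrophe_death_share(events: list[FateEvent], total_deaths: int) -> float:
    """Mitotic-catastrophe deaths as a fraction of all death events."""
    if total_deaths <= 0:
        return float("nan")
    n_cat = sum(e.outcome == "MITOTIC_CATASTROPHE" for e in events)
    return n_cat / total_deaths


# ---------------------------------------------------------------------------
# truth-matched scoring (synthetic movies)

_TRUTH_OUTCOME = {
    ("DIVISION", ""): "SUCCESSFUL_DIVISION",
    ("DEATH", "catastrophe"): "MITOTIC_CATASTROPHE",
    ("SLIPPAGE", ""): "MITOTIC_SLIPPAGE",
}


def match_fates(
    events: list[FateEvent],
    tracks: list[Track],
    event_log: pd.DataFrame,
    frame_tolerance: int = 3,
) -> dict:
    """Score classified fates against a simulator event log.

    A truth event matches a predicted event when the predicted track contains
    the truth parent nucleus near the event frame and the outcomes agree.
    Returns matched / total counts and accuracy over mitotic truth events.
    """
    by_id = {t.track_id: t for t in tracks}
    pred = list(events)
    n_total = 0
    n_correct = 0
    for _, row in event_log.iterrows():
        key = (row["event"], row.get("detail", "") or "")
        outcome = _TRUTH_OUTCOME.get(key)
        if outcome is None:
            continue  # non-mitotic deaths are not fate events
        n_total += 1
        parent = row["parent_id"]
        f_truth = int(row["frame"])
        hit = None
        for k, e in enumerate(pred):
            track = by_id[e.track_id]
            cells_near = {
                cid for f, cid in track.points
                if abs(f - f_truth) <= frame_tolerance
            }
            if parent in cells_near and abs(e.frame_start - f_truth) <= frame_tolerance:
                hit = k
                break
        if hit is None:
            continue
        if pred.pop(hit).outcome == outcome:
            n_correct += 1
    return {
        "n_truth_events": n_total,
        "n_correct": n_correct,
        "accuracy": (n_correct / n_total) if n_total else float("nan"),
    }


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tidy track table (one row per observation) plus lineage columns."""
    rows = []
    for t in tracks:
        for f, cid in t.points:
            rows.append(
                {"track_id": t.track_id, "frame": f, "cell_id": cid,
                 "parent_track": t.parent_track, "end_reason": t.end_reason}
            )
    return pd.DataFrame(rows)
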