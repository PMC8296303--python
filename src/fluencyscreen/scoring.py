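"""Index scoring of timed verbal-fluency transcripts.

A 60-second categorical fluency trial yields an ordered list of timed
tokens. Scoring reduces that list to a total score and seven indices:

1. **total** — number of correct (first-occurrence, in-lexicon) responses;
2. **first-half** — correct responses with onset in the first half of the
   scoring window;
3. **second-half** — correct responses in the last half;
4. **perseveration** — repetitions of any earlier response, correct or not;
5. **intrusion** — first occurrences of out-of-category (non-animal) tokens;
6. **clustering** — mean cluster size, a cluster being a maximal run of
   successive correct responses sharing an animal subcategory and its size
   the member count minus one;
7. **switching** — number of transitions between clusters (clusters − 1).

Perseverations are detected by canonical form when the token is in the
lexicon (so "puppy" after "dog" repeats), and by case-folded raw token
otherwise (so a repeated non-animal word counts as a perseveration, not a
second intrusion).

Cluster segmentation by default runs over correct responses only —
intervening errors neither join nor break a cluster — and uses
running-intersection semantics: the run extends while the intersection of
the subcategory sets of all its members stays non-empty. Both choices are
configurable (``errors_break_clusters``, ``chain_mode="pairwise"``).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from .taxonomy import UNKNOWN, Taxonomy, normalize_token

__all__ = [
    "CORRECT",
    "PERSEVERATION",
    "INTRUSION",
    "TimedResponse",
    "Transcript",
    "LabeledResponse",
    "Cluster",
    "IndexScores",
    "TranscriptError",
    "label_responses",
    "segment_clusters",
    "compute_index_scores",
    "read_transcripts_csv",
    "read_transcripts_jsonl",
    "write_transcripts_jsonl",
    "scores_to_row",
    "write_scores_csv",
    "SCORE_COLUMNS",
]

CORRECT = "correct"
PERSEVERATION = "perseveration"
INTRUSION = "intrusion"


class TranscriptError(ValueError):
    """Invalid transcript structure (onset order, duration, empty tokens)."""


@dataclass(frozen=True)
class TimedResponse:
    """One spoken token with its onset in seconds from task start.

    ``onset`` may be None for untimed transcripts; half scores are then
    unavailable unless an index-based fallback split is requested.
    """

    raw: str
    onset: float | None
    position: int

    def __post_init__(self) -> None:
        if self.onset is not None and self.onset < 0:
            raise TranscriptError(f"negative onset at position {self.position}")


@dataclass(frozen=True)
class Transcript:
    """Ordered timed responses of one fluency-test administration."""

    participant_id: str
    responses: tuple[TimedResponse, ...]
    duration: float = 60.0
    administration_index: int = 1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise TranscriptError("duration must be positive")
        prev = -math.inf
        for i, r in enumerate(self.responses):
            if r.position != i:
                raise TranscriptError(f"positions must be 0..n-1 (got {r.position} at {i})")
            if r.onset is not None:
                if r.onset > self.duration:
                    raise TranscriptError(
                        f"onset {r.onset} exceeds duration {self.duration}"
                    )
                if r.onset < prev:
                    raise TranscriptError("onsets must be nondecreasing")
                prev = r.onset

    @classmethod
    def from_tokens(
        cls,
        tokens: Sequence[str],
        onsets: Sequence[float] | None = None,
        participant_id: str = "anon",
        duration: float = 60.0,
        administration_index: int = 1,
    ) -> "Transcript":
        """Convenience constructor from parallel token/onset sequences."""
        if onsets is None:
            resp = tuple(
                TimedResponse(tok, None, i) for i, tok in enumerate(tokens)
            )
        else:
            resp = tuple(
                TimedResponse(tok, float(t), i)
                for i, (tok, t) in enumerate(zip(tokens, onsets, strict=True))
            )
        return cls(participant_id, resp, duration, administration_index)

    @property
    def timed(self) -> bool:
        return all(r.onset is not None for r in self.responses)


@dataclass(frozen=True)
class LabeledResponse:
    response: TimedResponse
    canonical: str  # canonical token, or UNKNOWN for non-animal words
    label: str  # CORRECT / PERSEVERATION / INTRUSION
    subcategories: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class Cluster:
    """A maximal run of consecutive correct responses sharing a subcategory.

    ``size`` is the member count minus one, so singleton clusters have
    size 0. ``shared_subcategories`` is the running intersection over all
    members (non-empty for multi-member clusters by construction).
    """

    member_positions: tuple[int, ...]
    shared_subcategories: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_positions) - 1


def label_responses(
    transcript: Transcript, taxonomy: Taxonomy
) -> list[LabeledResponse]:
    """Assign correct/perseveration/intrusion labels to every response.

    A response is a perseveration when its identity key — canonical form
    for in-lexicon tokens, case-folded raw token otherwise — has already
    occurred, regardless of whether that earlier occurrence was correct.
    Otherwise it is correct if in-lexicon, an intrusion if not.
    """
    seen: set[str] = set()
    out: list[LabeledResponse] = []
    for resp in transcript.responses:
        canonical = normalize_token(resp.raw, taxonomy)
        key = canonical if canonical != UNKNOWN else resp.raw.strip().casefold()
        if key in seen:
            label = PERSEVERATION
        elif canonical != UNKNOWN:
            label = CORRECT
        else:
            label = INTRUSION
        seen.add(key)
        subs = (
            taxonomy.subcategories_of(canonical)
            if canonical != UNKNOWN
            else frozenset()
        )
        out.append(LabeledResponse(resp, canonical, label, subs))
    return out


def segment_clusters(
    labeled: Sequence[LabeledResponse],
    taxonomy: Taxonomy,
    *,
    errors_break_clusters: bool = False,
    chain_mode: Literal["intersection", "pairwise"] = "intersection",
) -> list[Cluster]:
    """Partition the correct responses into maximal subcategory runs.

    Scans left to right and extends the current run while it remains
    subcategory-consistent; the greedy left-maximal partition is the unique
    one whose run lengths are lexicographically largest, because any prefix
    of a consistent run is itself consistent.

    ``chain_mode="intersection"`` (default) keeps the running intersection
    of member subcategory sets non-empty; ``"pairwise"`` only requires each
    adjacent pair to share a subcategory. With ``errors_break_clusters``
    an intervening perseveration or intrusion terminates the current run.
    """
    if chain_mode not in ("intersection", "pairwise"):
        raise ValueError(f"unknown chain_mode {chain_mode!r}")
    clusters: list[Cluster] = []
    run: list[LabeledResponse] = []
    inter: frozenset[str] = frozenset()

    def flush() -> None:
        nonlocal run, inter
        if run:
            clusters.append(
                Cluster(
                    tuple(r.response.position for r in run),
                    inter if len(run) > 1 else run[0].subcategories,
                )
            )
        run, inter = [], frozenset()

    for item in labeled:
        if item.label != CORRECT:
            if errors_break_clusters:
                flush()
            continue
        if not run:
            run, inter = [item], item.subcategories
            continue
        if chain_mode == "intersection":
            new_inter = inter & item.subcategories
        else:
            new_inter = run[-1].subcategories & item.subcategories
        if new_inter:
            run.append(item)
            inter = new_inter
        else:
            flush()
            run, inter = [item], item.subcategories
    flush()
    return clusters


@dataclass(frozen=True)
class IndexScores:
    """Total plus the seven fluency indices for one administration.

    ``first_half``/``second_half`` are None for untimed transcripts scored
    without the index-split fallback. ``clustering`` is the mean cluster
    size over all clusters, 0.0 when there are none (mute transcript;
    flagged by ``total == 0``).
    """

    total: int
    first_half: int | None
    second_half: int | None
    perseveration: int
    intrusion: int
    clustering: float
    switching: int
    window: float

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "first_half": self.first_half,
            "second_half": self.second_half,
            "perseveration": self.perseveration,
            "intrusion": self.intrusion,
            "clustering": self.clustering,
            "switching": self.switching,
            "window": self.window,
        }


def compute_index_scores(
    transcript: Transcript,
    taxonomy: Taxonomy,
    window: float = 60.0,
    *,
    untimed_index_split: bool = False,
    errors_break_clusters: bool = False,
    chain_mode: Literal["intersection", "pairwise"] = "intersection",
) -> IndexScores:
    """Score one transcript within the first *window* seconds.

    Responses with onset beyond the window are discarded before any
    labelling, so a repetition whose first occurrence falls outside the
    window counts as a first occurrence inside it. The half boundary is
    half-open: onset strictly below window/2 goes to the first half, onset
    equal to window/2 to the second.

    For untimed transcripts (any onset missing) half scores are reported
    as None unless ``untimed_index_split`` is set, in which case the first
    ``ceil(n/2)`` responses of the response list stand in for the first
    30 s.
    """
    if not (window > 0):
        raise ValueError("window must be positive")
    kept = [r for r in transcript.responses if r.onset is None or r.onset <= window]
    sub = Transcript(
        transcript.participant_id,
        tuple(
            TimedResponse(r.raw, r.onset, i) for i, r in enumerate(kept)
        ),
        duration=max(transcript.duration, window),
        administration_index=transcript.administration_index,
    )
    labeled = label_responses(sub, taxonomy)
    correct = [l for l in labeled if l.label == CORRECT]
    total = len(correct)
    perseveration = sum(1 for l in labeled if l.label == PERSEVERATION)
    intrusion = sum(1 for l in labeled if l.label == INTRUSION)

    timed = all(l.response.onset is not None for l in labeled)
    first_half: int | None
    second_half: int | None
    if timed:
        half = window / 2.0
        first_half = sum(1 for l in correct if l.response.onset < half)
        second_half = total - first_half
    elif untimed_index_split:
        cut = math.ceil(len(labeled) / 2)
        first_half = sum(1 for l in correct if l.response.position < cut)
        second_half = total - first_half
    else:
        first_half = second_half = None

    clusters = segment_clusters(
        labeled,
        taxonomy,
        errors_break_clusters=errors_break_clusters,
        chain_mode=chain_mode,
    )
    clustering = (
        sum(c.size for c in clusters) / len(clusters) if clusters else 0.0
    )
    switching = max(len(clusters) - 1, 0)
    return IndexScores(
        total=total,
        first_half=first_half,
        second_half=second_half,
        perseveration=perseveration,
        intrusion=intrusion,
        clustering=clustering,
        switching=switching,
        window=window,
    )


# ---------------------------------------------------------------------------
# Transcript / score file formats
# ---------------------------------------------------------------------------

#: Column order of the flat scores CSV (one row per administration).
SCORE_COLUMNS = [
    "participant_id",
    "administration",
    "total",
    "first_half",
    "second_half",
    "perseveration",
    "intrusion",
    "clustering",
    "switching",
    "window",
]


def read_transcripts_csv(path: str | Path) -> list[Transcript]:
    """Read transcripts from a long CSV.

    Columns: participant_id, administration_index, position, token, onset_s
    (onset_s may be blank for untimed data); one row per response.
    """
    groups: dict[tuple[str, int], list[tuple[int, str, float | None]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"participant_id", "administration_index", "position", "token"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TranscriptError(
                f"{path}: transcript CSV needs columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (row["participant_id"], int(row["administration_index"]))
                onset_raw = (row.get("onset_s") or "").strip()
                onset = float(onset_raw) if onset_raw else None
                groups.setdefault(key, []).append(
                    (int(row["position"]), row["token"], onset)
                )
            except (KeyError, ValueError) as exc:
                raise TranscriptError(f"{path}:{lineno}: bad row ({exc})") from exc
    out = []
    for (pid, adm), rows in groups.items():
        rows.sort(key=lambda t: t[0])
        out.append(
            Transcript(
                pid,
                tuple(
                    TimedResponse(tok, onset, i)
                    for i, (_, tok, onset) in enumerate(rows)
                ),
                administration_index=adm,
            )
        )
    return out


def read_transcripts_jsonl(path: str | Path) -> list[Transcript]:
    """Read transcripts from JSON lines, one administration per line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                resp = tuple(
                    TimedResponse(r["token"], r.get("onset_s"), i)
                    for i, r in enumerate(obj["responses"])
                )
                out.append(
                    Transcript(
                        obj["participant_id"],
                        resp,
                        duration=float(obj.get("duration_s", 60.0)),
                        administration_index=int(obj.get("administration", 1)),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise TranscriptError(f"{path}:{lineno}: bad record ({exc})") from exc
    return out


def write_transcripts_jsonl(
    transcripts: Iterable[Transcript], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in transcripts:
            obj = {
                "participant_id": t.participant_id,
                "administration": t.administration_index,
                "duration_s": t.duration,
                "responses": [
                    {"token": r.raw, "onset_s": r.onset} for r in t.responses
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def scores_to_row(transcript: Transcript, scores: IndexScores) -> dict:
    row = {"participant_id": transcript.participant_id,
           "administration": transcript.administration_index}
    row.update(scores.as_dict())
    return row


def write_scores_csv(rows: Iterable[dict], path: str | Path) -> None:
    """Write index-score rows as a flat CSV with a mandatory header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=SCORE_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: ("" if row.get(k) is None else row.get(k))
                             for k in SCORE_COLUMNS})
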