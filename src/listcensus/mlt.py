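"""The MacKinnon Lists Technique (MLT).

MLT is a sampling-with-replacement survey method: the chronological stream of
species records from a survey (here, one video) is chopped into fixed-length
*list samples* of ``k`` unique species (k = 5 by default for reef fish; 10 is
common for birds).  A species may recur across lists but never within one;
each completed list is one sampling unit, so a single video can yield several
samples.

Pipeline implemented here:

1. :func:`build_master_list` — condense a video's detection events into a
   chronologically ordered *master list*, re-recording a species only after it
   has been absent for more than a re-detection gap (3 minutes by default).
2. :func:`segment_lists` — walk the master list, filling lists of ``k`` unique
   species; the trailing partial list (< k species) is returned separately.
3. :func:`pool_partials` — within one habitat, concatenate the partial lists
   from its videos and re-segment them into *additional* (pooled) lists so no
   master-list information is discarded for richness estimation.  Pooled lists
   are flagged: they enter richness work but are excluded from multivariate
   analysis, where video is a random factor.
4. :func:`incidence_matrix` / :func:`mlt_abundance` — lists x species
   presence matrix and the list-count / fraction-of-lists abundance indices.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .events import Habitat, habitat_of

#: video_id marker for pooled (cross-video) lists.
POOLED = "<pooled>"

DEFAULT_K = 5
DEFAULT_GAP_S = 180.0


@dataclass(frozen=True)
class MasterList:
    """Chronologically ordered qualifying species records for one video."""

    video_id: str
    records: tuple[tuple[str, float], ...]  # (species, time_s), time non-decreasing

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.records)


@dataclass(frozen=True)
class ListSample:
    """One MLT sampling unit: an ordered set of <= k unique species."""

    sample_id: str
    habitat: Habitat
    video_id: str  # POOLED for pooled lists
    ordinal: int  # 1-based position within its source video / pooled stream
    species_seq: tuple[str, ...]
    k: int
    pooled: bool = False

    def __post_init__(self):
        if len(set(self.species_seq)) != len(self.species_seq):
            raise ValueError(f"{self.sample_id}: duplicate species within a list")
        if len(self.species_seq) > self.k:
            raise ValueError(f"{self.sample_id}: more than k={self.k} species")
        if self.pooled and self.video_id != POOLED:
            raise ValueError(f"{self.sample_id}: pooled list must carry the POOLED marker")

    @property
    def complete(self) -> bool:
        return len(self.species_seq) == self.k

    def __len__(self) -> int:
        return len(self.species_seq)


def build_master_list(events: pd.DataFrame, gap_s: float = DEFAULT_GAP_S) -> MasterList:
    """Condense one video's time-sorted events into a master list.

    A species' first detection is always recorded.  A later detection is
    recorded iff strictly more than ``gap_s`` seconds have passed since that
    species' *previous detection* (recorded or not): detections approximate
    presence in the field of view, so the gap clock restarts at every sighting.
    With ``gap_s = 0`` every detection qualifies; with ``gap_s`` longer than
    the video each species appears at most once.
    """
    vids = events["video_id"].unique()
    if len(vids) > 1:
        raise ValueError(f"build_master_list expects one video, got {sorted(vids)}")
    video_id = str(vids[0]) if len(vids) else ""
    records: list[tuple[str, float]] = []
    last_seen: dict[str, float] = {}
    for row in events.itertuples(index=False):
        t = float(row.time_s)
        sp = row.species
        prev = last_seen.get(sp)
        if prev is None or t - prev > gap_s:
            records.append((sp, t))
        last_seen[sp] = t
    return MasterList(video_id=video_id, records=tuple(records))


def _segment_records(
    species_stream: Iterable[str], k: int
) -> tuple[list[tuple[str, ...]], tuple[str, ...]]:
    """Core segmentation walk shared by per-video lists and pooling."""
    complete: list[tuple[str, ...]] = []
    open_list: list[str] = []
    for sp in species_stream:
        if sp in open_list:  # duplicate inside the open list: skipped
            continue
        open_list.append(sp)
        if len(open_list) == k:
            complete.append(tuple(open_list))
            open_list = []
    return complete, tuple(open_list)


def segment_lists(
    master: MasterList,
    k: int = DEFAULT_K,
    habitat: Habitat | None = None,
    sample_prefix: str | None = None,
) -> tuple[list[ListSample], ListSample | None]:
    """Segment a master list into complete k-species lists plus a trailing partial.

    Records join the open list only if their species is not already in it;
    when the open list reaches ``k`` species it closes and a new one opens.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    prefix = sample_prefix if sample_prefix is not None else master.video_id
    complete_seqs, partial_seq = _segment_records(master.species, k)
    hab = habitat if habitat is not None else Habitat("", "")
    complete = [
        ListSample(
            sample_id=f"{prefix}:L{i + 1}",
            habitat=hab,
            video_id=master.video_id,
            ordinal=i + 1,
            species_seq=seq,
            k=k,
        )
        for i, seq in enumerate(complete_seqs)
    ]
    partial = None
    if partial_seq:
        partial = ListSample(
            sample_id=f"{prefix}:P",
            habitat=hab,
            video_id=master.video_id,
            ordinal=len(complete) + 1,
            species_seq=partial_seq,
            k=k,
        )
    return complete, partial


def pool_partials(
    partials: Sequence[ListSample],
    k: int = DEFAULT_K,
    order: str = "video_id",
) -> list[ListSample]:
    """Pool one habitat's partial lists into additional (pooled) lists.

    The partials are concatenated — by default in ascending ``video_id``,
    preserving each partial's internal order — into one record stream and
    re-segmented by the usual rule.  A final leftover shorter than ``k`` is
    kept as one last (incomplete) pooled list so every master-list record is
    used for richness estimation.
    """
    if not partials:
        return []
    habitats = {p.habitat for p in partials}
    if len(habitats) > 1:
        raise ValueError(f"pool_partials requires one habitat, got {sorted(habitats)}")
    habitat = next(iter(habitats))
    if order == "video_id":
        ordered = sorted(partials, key=lambda p: p.video_id)
    elif order == "given":
        ordered = list(partials)
    else:
        raise ValueError(f"unknown pooling order policy {order!r}")
    stream = [sp for p in ordered for sp in p.species_seq]
    complete_seqs, leftover = _segment_records(stream, k)
    seqs = complete_seqs + ([leftover] if leftover else [])
    return [
        ListSample(
            sample_id=f"{habitat.label}:A{i + 1}",
            habitat=habitat,
            video_id=POOLED,
            ordinal=i + 1,
            species_seq=seq,
            k=k,
            pooled=True,
        )
        for i, seq in enumerate(seqs)
    ]


def lists_for_survey(
    events: pd.DataFrame,
    videos: pd.DataFrame,
    k: int = DEFAULT_K,
    gap_s: float = DEFAULT_GAP_S,
    pooling_order: str = "video_id",
) -> list[ListSample]:
    """Full MLT sampling for a survey: per-video lists plus per-habitat pooled lists."""
    habitats = dict(zip(videos["video_id"], habitat_of(videos)))
    samples: list[ListSample] = []
    partials_by_habitat: dict[Habitat, list[ListSample]] = defaultdict(list)
    for vid, ev in events.groupby("video_id", sort=True):
        if vid not in habitats:
            raise ValueError(f"events reference unknown video {vid!r}")
        master = build_master_list(ev, gap_s=gap_s)
        complete, partial = segment_lists(master, k=k, habitat=habitats[vid])
        samples.extend(complete)
        if partial is not None:
            partials_by_habitat[habitats[vid]].append(partial)
    for habitat in sorted(partials_by_habitat, key=lambda h: h.label):
        samples.extend(pool_partials(partials_by_habitat[habitat], k=k, order=pooling_order))
    return samples


def incidence_matrix(
    samples: Sequence[ListSample], include_pooled: bool = True
) -> pd.DataFrame:
    """Binary lists x species occurrence matrix.

    ``include_pooled=True`` for richness estimation; ``False`` for the
    multivariate analysis, which excludes pooled lists.  Species absent from
    every retained sample are dropped.
    """
    kept = [s for s in samples if include_pooled or not s.pooled]
    species = sorted({sp for s in kept for sp in s.species_seq})
    data = [[1 if sp in s.species_seq else 0 for sp in species] for s in kept]
    return pd.DataFrame(data, index=[s.sample_id for s in kept], columns=species, dtype=int)


def q_profile(incidence: pd.DataFrame) -> pd.Series:
    """Q_j profile: number of species occurring in exactly j samples (j >= 1)."""
    counts = (incidence > 0).sum(axis=0)
    counts = counts[counts > 0]
    return counts.value_counts().sort_index()


def mlt_abundance(
    samples: Sequence[ListSample],
    scope: str = "per-habitat",
    species_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """List-count and fraction-of-lists abundance indices.

    Returns a DataFrame indexed by (scope value, species) with columns
    ``list_count`` (number of lists in scope containing the species) and
    ``list_fraction`` (list_count / lists in scope).
    """
    if not samples:
        raise ValueError("mlt_abundance: empty scope (no list samples)")
    if scope == "per-habitat":
        key = lambda s: s.habitat.label
    elif scope == "per-video":
        key = lambda s: s.video_id
    else:
        raise ValueError(f"unknown scope {scope!r}")
    groups: dict[str, list[ListSample]] = defaultdict(list)
    for s in samples:
        groups[key(s)].append(s)
    rows = []
    for g in sorted(groups):
        lists = groups[g]
        n_lists = len(lists)
        species = (
            sorted({sp for s in lists for sp in s.species_seq})
            if species_universe is None
            else list(species_universe)
        )
        for sp in species:
            count = sum(1 for s in lists if sp in s.species_seq)
            rows.append((g, sp, count, count / n_lists))
    out = pd.DataFrame(rows, columns=["scope", "species", "list_count", "list_fraction"])
    return out.set_index(["scope", "species"])


def lists_to_frame(samples: Sequence[ListSample]) -> pd.DataFrame:
    """Long-format export: one row per species per list."""
    rows = []
    for s in samples:
        for pos, sp in enumerate(s.species_seq, start=1):
            rows.append(
                (
                    s.sample_id,
                    s.habitat.label,
                    s.video_id,
                    s.ordinal,
                    s.pooled,
                    pos,
                    sp,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "habitat", "video_id", "ordinal", "pooled", "position", "species"],
    )


def frame_to_lists(frame: pd.DataFrame, k: int = DEFAULT_K) -> list[ListSample]:
    """Inverse of :func:`lists_to_frame`."""
    samples = []
    for sample_id, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("position")
        first = grp.iloc[0]
        label = str(first["habitat"])
        depth, status = label.split(" ", 1)
        samples.append(
            ListSample(
                sample_id=str(sample_id),
                habitat=Habitat(status.lower(), depth.lower()),
                video_id=str(first["video_id"]),
                ordinal=int(first["ordinal"]),
                species_seq=tuple(grp["species"]),
                k=k,
                pooled=bool(first["pooled"]),
            )
        )
    return samples
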