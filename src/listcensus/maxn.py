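"""MaxN relative-abundance index.

MaxN is, per species per video deployment, the maximum number of individuals
visible simultaneously.  It is the standard conservative abundance index for
baited remote underwater video because it cannot double-count an individual.
Here events are timestamped snapshots with a count in view, so MaxN is the
maximum single-event count per species.
"""

from __future__ import annotations

import pandas as pd

from .events import habitat_of


def compute_maxn(events: pd.DataFrame) -> pd.Series:
    """MaxN per species for one video's events (species with no events absent)."""
    vids = events["video_id"].unique()
    if len(vids) > 1:
        raise ValueError(f"compute_maxn expects one video, got {sorted(vids)}")
    if events.empty:
        return pd.Series(dtype=int, name="maxn")
    out = events.groupby("species")["n_individuals"].max().sort_index()
    out.name = "maxn"
    return out.astype(int)


def maxn_matrix(events: pd.DataFrame, videos: pd.DataFrame) -> pd.DataFrame:
    """Video x species MaxN matrix.

    Videos with no detections keep an all-zero row so habitat means divide by
    the number of deployments.
    """
    per_video = {
        vid: compute_maxn(ev) for vid, ev in events.groupby("video_id", sort=True)
    }
    species = sorted({sp for s in per_video.values() for sp in s.index})
    mat = pd.DataFrame(0, index=list(videos["video_id"]), columns=species, dtype=int)
    for vid, counts in per_video.items():
        if vid not in mat.index:
            raise ValueError(f"events reference unknown video {vid!r}")
        mat.loc[vid, counts.index] = counts.values
    mat.index.name = "video_id"
    return mat


def maxn_abundance(matrix: pd.DataFrame, videos: pd.DataFrame) -> pd.DataFrame:
    """Habitat-level MaxN indices: per species, summed and mean MaxN per deployment.

    The mean divides by the habitat's number of videos, so deployments where
    the species was absent pull the mean down (they contribute 0).
    """
    habitats = habitat_of(videos)
    labels = pd.Series([h.label for h in habitats], index=videos["video_id"].values)
    rows = []
    for label, vids in labels.groupby(labels):
        block = matrix.loc[vids.index]
        if block.empty:
            raise ValueError(f"habitat {label!r} has no videos")
        n = len(block)
        for sp in matrix.columns:
            total = int(block[sp].sum())
            rows.append((label, sp, total, total / n))
    out = pd.DataFrame(rows, columns=["habitat", "species", "sum_maxn", "mean_maxn"])
    return out.set_index(["habitat", "species"])
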