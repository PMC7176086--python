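"""Habitat-level summary tables from a published baited-video field comparison.

These are printed summaries from a reef-fish field evaluation that ran the
MacKinnon Lists Technique and MaxN side by side over four habitats
(Deep/Shallow x Fished/ROA).  They serve as worked inputs for the
method-comparison statistics (paired t-tests, final-rate-of-change stability
diagnostics, top-10 overlap and rank differences): the package recomputes
those statistics from these tables rather than shipping any raw survey data.
"""

from __future__ import annotations

HABITATS = ("Deep Fished", "Shallow Fished", "Deep ROA", "Shallow ROA")

#: Chao2 richness estimate per habitat, by method (species).
CHAO2_ESTIMATES = {
    "maxn": {"Deep Fished": 97.00, "Shallow Fished": 83.30, "Deep ROA": 51.54, "Shallow ROA": 54.42},
    "mlt": {"Deep Fished": 90.70, "Shallow Fished": 81.90, "Deep ROA": 39.04, "Shallow ROA": 61.37},
}

#: (final, penultimate) Chao2 estimates along the accumulation trajectory,
#: i.e. after the last and second-to-last sample.
CHAO2_TRAJECTORY_PAIRS = {
    "maxn": {
        "Deep Fished": (97.00, 93.18),
        "Shallow Fished": (83.30, 81.52),
        "Deep ROA": (51.54, 48.72),
        "Shallow ROA": (54.42, 52.76),
    },
    "mlt": {
        "Deep Fished": (90.70, 91.13),
        "Shallow Fished": (81.90, 82.44),
        "Deep ROA": (39.04, 39.21),
        "Shallow ROA": (61.37, 60.23),
    },
}

#: Printed final rate of change of the Chao2 estimate (species per sample).
FINAL_RATE = {
    "maxn": {"Deep Fished": 3.82, "Shallow Fished": 1.78, "Deep ROA": 2.82, "Shallow ROA": 1.66},
    "mlt": {"Deep Fished": 0.43, "Shallow Fished": 0.54, "Deep ROA": 0.17, "Shallow ROA": 1.14},
}

#: Number of samples per habitat: videos for MaxN; list samples for MLT
#: (pooled "additional" lists in the second element).
SAMPLE_COUNTS = {
    "maxn": {"Deep Fished": 14, "Shallow Fished": 10, "Deep ROA": 5, "Shallow ROA": 5},
    "mlt": {
        "Deep Fished": (53, 6),
        "Shallow Fished": (54, 4),
        "Deep ROA": (14, 1),
        "Shallow ROA": (27, 2),
    },
}

#: Most-abundant-species table: per habitat and method, the printed abundance
#: index (summed MaxN / MLT list count) and, where the species made the
#: method's printed top ten, its printed rank.
#: Shape: {habitat: {species: ((maxn_count, maxn_rank), (mlt_count, mlt_rank))}}
#: rank is None for unranked species.
TOP_SPECIES = {
    "Deep Fished": {
        "Chaetodon assarius": ((23, 8), (20, 8)),
        "Choerodon rubescens": ((39, 4), (30, 3)),
        "Chromis westaustralis": ((23, 7), (23, 5)),
        "Coris auricularis": ((37, 5), (22, 6)),
        "Pagrus auratus": ((67, 2), (26, 4)),
        "Parupeneus spilurus": ((20, 9), (18, None)),
        "Pentapodus nagasakiensis": ((16, None), (16, 10)),
        "Plectropomus leopardus": ((46, 3), (42, 2)),
        "Pseudocaranx spp": ((68, 1), (62, 1)),
        "Scarus ghobban": ((20, 10), (18, 9)),
        "Scarus schlegeli": ((27, 6), (21, 7)),
    },
    "Shallow Fished": {
        "Chlorurus sordidus": ((69, 2), (58, 2)),
        "Choerodon rubescens": ((18, 9), (16, 10)),
        "Chromis westaustralis": ((137, 1), (134, 1)),
        "Coris auricularis": ((38, 5), (24, 8)),
        "Dascyllus trimaculatus": ((28, 8), (26, 7)),
        "Gymnothorax woodwardi": ((8, None), (15, 9)),
        "Plectropomus leopardus": ((30, 7), (30, 4)),
        "Pseudocaranx spp": ((56, 3), (56, 3)),
        "Scarus schlegeli": ((33, 6), (26, 6)),
        "Thalassoma lunare": ((42, 4), (29, 5)),
        "Thalassoma lutescens": ((17, 10), (16, None)),
    },
    "Deep ROA": {
        "Chaetodon lunula": ((3, 9), (4, None)),
        "Chaetodon plebeius": ((3, 10), (2, 9)),
        "Chlorurus sordidus": ((5, 7), (5, 6)),
        "Choerodon rubescens": ((7, 4), (6, 5)),
        "Chromis westaustralis": ((64, 1), (63, 1)),
        "Gymnothorax woodwardi": ((4, 8), (4, 7)),
        "Lethrinus nebulosus": ((6, 6), (3, 8)),
        "Pagrus auratus": ((7, 5), (7, 4)),
        "Plectropomus leopardus": ((12, 2), (11, 2)),
        "Scombridae spp": ((9, 3), (8, 3)),
        "Stethojulis strigiventer": ((2, None), (2, 10)),
    },
    "Shallow ROA": {
        "Chaetodon lunula": ((11, 8), (6, 9)),
        "Chlorurus sordidus": ((13, 6), (13, 5)),
        "Choerodon rubescens": ((12, 7), (12, 6)),
        "Chromis westaustralis": ((218, 1), (203, 1)),
        "Kyphosus cornelii": ((42, 2), (43, 2)),
        "Lethrinus nebulosus": ((17, 4), (17, 4)),
        "Plectropomus leopardus": ((9, 9), (12, 8)),
        "Scarus schlegeli": ((7, 10), (6, 10)),
        "Scombridae spp": ((19, 3), (19, 3)),
        "Thalassoma lunare": ((16, 5), (10, 7)),
    },
}


def top_counts(habitat: str, method: str) -> dict[str, float]:
    """Printed abundance-index values for one habitat and method."""
    col = 0 if method == "maxn" else 1
    return {sp: vals[col][0] for sp, vals in TOP_SPECIES[habitat].items() if vals[col][0] > 0}


def top_rank_scores(habitat: str, method: str) -> dict[str, float]:
    """Printed top-ten ranks recoded as descending scores (rank 1 -> largest).

    Only ranked species appear; feeding these to the top-k selection
    reproduces each method's printed top-ten list exactly, tie-free.
    """
    col = 0 if method == "maxn" else 1
    out = {}
    for sp, vals in TOP_SPECIES[habitat].items():
        rank = vals[col][1]
        if rank is not None:
            out[sp] = 11 - rank
    return out
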