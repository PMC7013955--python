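"""Published summary rows of the two Australian AUV benthic surveys.

These are the per-site and per-year label counts of the Benthoz15 and
Rottnest Island point-annotation campaigns as published (points and images
per group). They serve as reference inputs for dataset-summary arithmetic:
:func:`expand_counts` turns a row of counts into a stand-in annotation
table with exactly that many points and images, so :func:`~kelpcover.annotations.summarize`
can be checked against the published totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotations import ANNOTATION_COLUMNS, AnnotationTable

__all__ = ["BENTHOZ15_SITE_ROWS", "ROTTNEST_YEAR_ROWS", "expand_counts"]

#: (site, n_points, n_images) per survey location, Benthoz15 campaign.
BENTHOZ15_SITE_ROWS = (
    ("Abrolhos Islands", 119_273, 2377),
    ("Tasmania", 88_900, 1778),
    ("Rottnest Island", 63_600, 1272),
    ("Jurien Bay", 55_050, 1101),
    ("Solitary Islands", 30_700, 1228),
    ("Batemans Bay", 24_825, 993),
    ("Port Stevens", 15_600, 624),
    ("South East Queensland", 10_020, 501),
)

#: (year, n_images, n_points) per survey year, Rottnest Island campaign.
ROTTNEST_YEAR_ROWS = (
    (2010, 1680, 84_000),
    (2011, 1680, 84_000),
    (2012, 1033, 51_650),
    (2013, 1563, 78_150),
)


def expand_counts(
    rows: tuple[tuple, ...],
    kind: str,
) -> AnnotationTable:
    """Stand-in per-point table reproducing published group counts exactly.

    ``kind`` is ``"site"`` (rows of (site, n_points, n_images)) or
    ``"year"`` (rows of (year, n_images, n_points)). Points are spread over
    the stated number of distinct synthetic image ids as evenly as the
    remainder allows; labels and coordinates are placeholders (the summary
    arithmetic only counts rows and distinct images).
    """
    frames = []
    for row in rows:
        if kind == "site":
            site, n_points, n_images = row
            year = 0
        elif kind == "year":
            year, n_images, n_points = row
            site = ""
        else:
            raise ValueError(f"kind must be 'site' or 'year', got {kind!r}")
        # points per image: n_points = n_images * q + r, first r images get q+1
        q, r = divmod(n_points, n_images)
        per_image = np.full(n_images, q, dtype=np.int64)
        per_image[:r] += 1
        image_ids = np.repeat(
            [f"{site or year}/im{i:05d}" for i in range(n_images)], per_image
        )
        within = np.concatenate([np.arange(k) for k in per_image])
        frames.append(
            pd.DataFrame(
                {
                    "image_id": image_ids,
                    "x": within,  # distinct (image, x, y) per point
                    "y": 0,
                    "label": "unlabelled",
                    "site": str(site),
                    "year": int(year),
                    "depth_m": np.nan,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)[list(ANNOTATION_COLUMNS)]
    return AnnotationTable(df, provenance=f"published {kind} counts")
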