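"""Default per-class marker summaries for the synthetic-cohort generator.

Each entry maps a marker to per-class ``(median, q25, q75)`` triples.
``MARKER_SUMMARIES_4CLASS`` covers severity classes 0-3 (class 0 = healthy
controls); ``MARKER_SUMMARIES_3CLASS`` covers the merged labelling where
healthy+mild form class 0.  Values are published cohort summary statistics
for a 97-participant study population and serve only to give the generator
realistic per-class marginals; they are not re-estimated at run time.
"""

from __future__ import annotations

#: Marker columns in canonical order, with measurement units.
MARKER_UNITS: dict[str, str] = {
    "mch": "pg",
    "lymphocytes": "x10^9/L",
    "neutrophils": "x10^9/L",
    "platelets": "x10^9/L",
    "sodium": "mmol/L",
    "bicarbonate": "mmol/L",
    "urea": "mmol/L",
    "serum_creatinine": "umol/L",
    "alp": "U/L",
    "pth": "pmol/L",
    "urinary_creatinine_24h": "mmol/24h",
    "activin_b": "pg/mL",
    "dass_total": "score",
    "epworth": "score",
    "age": "years",
}

MARKER_NAMES: tuple[str, ...] = tuple(MARKER_UNITS)

#: Markers subject to collection non-compliance (24-h urine based).
URINE_MARKERS: tuple[str, ...] = ("urinary_creatinine_24h",)

#: Default panel fed to the severity model.
DEFAULT_FEATURE_PANEL: tuple[str, ...] = (
    "mch",
    "lymphocytes",
    "urea",
    "alp",
    "urinary_creatinine_24h",
    "activin_b",
)

#: 4-class cohort sizes (class 0 = healthy controls).
CLASS_SIZES_4CLASS: dict[int, int] = {0: 17, 1: 19, 2: 38, 3: 23}

# marker -> {class: (median, q25, q75)}.  A couple of source sodium rows had
# a median printed below its q25; the median is clamped into [q25, q75] so
# every triple satisfies q25 <= median <= q75.
MARKER_SUMMARIES_4CLASS: dict[str, dict[int, tuple[float, float, float]]] = {
    "mch": {
        0: (30.8, 29.4, 31.5),
        1: (30.6, 30.0, 31.2),
        2: (30.3, 28.7, 31.0),
        3: (30.9, 30.2, 31.6),
    },
    "lymphocytes": {
        0: (2.3, 1.9, 2.6),
        1: (1.8, 1.5, 2.8),
        2: (2.0, 1.5, 2.3),
        3: (2.1, 1.8, 2.5),
    },
    "neutrophils": {
        0: (4.3, 3.4, 5.4),
        1: (3.6, 2.6, 4.8),
        2: (4.1, 2.9, 4.9),
        3: (3.5, 2.5, 4.5),
    },
    "platelets": {
        0: (264.0, 235.0, 297.0),
        1: (244.0, 203.0, 308.0),
        2: (258.0, 227.0, 307.0),
        3: (273.0, 251.0, 300.0),
    },
    "sodium": {
        0: (141.0, 139.5, 142.0),
        1: (141.5, 141.5, 142.0),  # clamped
        2: (141.0, 141.0, 142.0),
        3: (141.0, 141.0, 142.0),  # clamped
    },
    "bicarbonate": {
        0: (29.0, 28.0, 30.5),
        1: (30.0, 27.0, 32.3),
        2: (29.0, 28.0, 31.5),
        3: (29.0, 27.0, 30.0),
    },
    "urea": {
        0: (5.5, 4.75, 7.9),
        1: (5.1, 3.8, 5.6),
        2: (5.4, 4.0, 6.1),
        3: (4.5, 4.0, 5.1),
    },
    "serum_creatinine": {
        0: (76.0, 67.5, 82.5),
        1: (73.5, 68.0, 93.0),
        2: (76.0, 66.5, 85.5),
        3: (71.0, 65.0, 77.0),
    },
    "alp": {
        0: (65.0, 52.0, 77.5),
        1: (64.0, 53.0, 78.0),
        2: (72.0, 62.0, 84.5),
        3: (60.0, 45.0, 74.0),
    },
    "pth": {
        0: (7.7, 5.2, 8.8),
        1: (5.7, 3.7, 6.8),
        2: (5.6, 3.7, 7.5),
        3: (5.2, 2.9, 6.5),
    },
    "urinary_creatinine_24h": {
        0: (13.1, 10.8, 17.2),
        1: (10.0, 7.8, 14.4),
        2: (9.4, 7.7, 12.2),
        3: (10.2, 9.2, 10.9),
    },
    "activin_b": {
        0: (114.19, 92.21, 162.24),
        1: (89.48, 59.97, 147.17),
        2: (79.97, 71.00, 106.97),
        3: (89.74, 70.48, 133.19),
    },
    "dass_total": {
        0: (8.0, 4.0, 11.5),
        1: (25.0, 10.3, 36.3),
        2: (28.0, 15.3, 47.3),
        3: (28.0, 16.3, 54.5),
    },
    "epworth": {
        0: (4.0, 3.0, 6.5),
        1: (4.0, 1.5, 5.8),
        2: (7.0, 3.0, 12.0),
        3: (6.5, 3.3, 10.8),
    },
    "age": {
        0: (41.0, 29.0, 51.0),
        1: (45.0, 39.0, 50.0),
        2: (55.0, 43.0, 61.5),
        3: (42.0, 36.0, 53.0),
    },
}

#: Merged-class summaries (class 0 = healthy + mild, 1 = moderate, 2 = severe).
MARKER_SUMMARIES_3CLASS: dict[str, dict[int, tuple[float, float, float]]] = {
    "mch": {0: (30.8, 29.9, 31.4), 1: (30.2, 28.8, 30.9), 2: (30.9, 30.2, 31.6)},
    "lymphocytes": {0: (2.0, 1.6, 2.6), 1: (1.95, 1.5, 2.2), 2: (2.1, 1.8, 2.5)},
    "neutrophils": {0: (3.9, 2.8, 5.2), 1: (4.1, 2.9, 4.9), 2: (3.5, 2.5, 4.5)},
    "platelets": {
        0: (254.5, 214.3, 305.0),
        1: (256.5, 219.5, 305.8),
        2: (273.0, 251.0, 300.0),
    },
    "sodium": {0: (141.0, 140.0, 142.0), 1: (141.5, 141.0, 142.0), 2: (141.0, 140.0, 142.0)},
    "bicarbonate": {0: (29.0, 28.0, 31.0), 1: (29.5, 28.0, 31.3), 2: (29.0, 27.0, 30.0)},
    "urea": {0: (5.1, 4.6, 6.4), 1: (5.4, 3.9, 6.1), 2: (4.5, 4.0, 5.1)},
    "serum_creatinine": {
        0: (74.0, 69.0, 84.0),
        1: (76.0, 66.8, 84.8),
        2: (71.0, 65.0, 77.0),
    },
    "alp": {0: (64.0, 53.3, 77.5), 1: (72.5, 62.0, 85.3), 2: (60.0, 45.0, 74.0)},
    "pth": {0: (5.9, 4.7, 8.4), 1: (5.6, 3.7, 8.4), 2: (5.2, 2.9, 6.5)},
    "urinary_creatinine_24h": {
        0: (12.7, 8.3, 15.3),
        1: (9.4, 7.7, 12.0),
        2: (10.2, 9.2, 10.9),
    },
    "activin_b": {
        0: (103.36, 78.57, 148.78),
        1: (80.73, 71.27, 107.81),
        2: (89.74, 70.48, 133.19),
    },
    "dass_total": {0: (11.0, 6.5, 29.5), 1: (28.0, 15.3, 47.3), 2: (28.0, 16.3, 54.5)},
    "epworth": {0: (4.0, 3.0, 6.0), 1: (7.0, 3.0, 12.0), 2: (6.5, 3.3, 10.8)},
    "age": {0: (43.0, 36.3, 50.0), 1: (54.5, 43.0, 61.3), 2: (42.0, 36.0, 53.0)},
}
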