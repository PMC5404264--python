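"""Benchmark confusion matrices of the myoepithelial classification task.

These are the published reference confusion matrices for classifying
myoepithelial nuclei into Normal / UDH / LG-DCIS / HG-DCIS at three
aggregation levels (cell, duct, patient) on the two stains (p63
immunohistochemistry and HE), transcribed as fixed count tables.  The
evaluation layer recomputes every reported accuracy and kappa index from
these counts; nothing here stores a metric value.
"""

from __future__ import annotations

import numpy as np

from .core import CLASSES
from .evaluate import ConfusionMatrix, metrics_pair

_LEVELS = ("cell", "duct", "patient")
_STAINS = ("p63", "he")

_RAW: dict[tuple[str, str], list[list[int]]] = {
    ("cell", "p63"): [
        [625, 150, 31, 18],
        [265, 330, 84, 13],
        [115, 103, 293, 34],
        [145, 91, 84, 40],
    ],
    ("cell", "he"): [
        [263, 85, 30, 8],
        [149, 133, 34, 5],
        [57, 24, 110, 8],
        [52, 35, 61, 18],
    ],
    ("duct", "p63"): [
        [13, 0, 0, 1],
        [1, 12, 2, 1],
        [0, 3, 13, 5],
        [2, 2, 2, 13],
    ],
    ("duct", "he"): [
        [9, 4, 0, 1],
        [2, 8, 2, 3],
        [1, 1, 18, 1],
        [0, 2, 7, 10],
    ],
    ("patient", "p63"): [
        [7, 0, 0, 0],
        [0, 5, 0, 0],
        [0, 0, 4, 1],
        [0, 1, 0, 4],
    ],
    ("patient", "he"): [
        [5, 1, 0, 1],
        [0, 4, 1, 0],
        [0, 0, 5, 0],
        [0, 0, 1, 4],
    ],
}


def reference_confusions() -> dict[tuple[str, str], ConfusionMatrix]:
    """The six reference matrices, keyed by (level, stain)."""
    return {
        key: ConfusionMatrix(np.array(counts), CLASSES)
        for key, counts in _RAW.items()
    }


def reference_metrics() -> dict[str, dict]:
    """Recompute accuracy/kappa (4-class and Benign-vs-DCIS) per matrix."""
    out = {}
    for (level, stain), cm in reference_confusions().items():
        out[f"{level}_{stain}"] = {"n": cm.total, **metrics_pair(cm)}
    return out


def format_reference_report() -> str:
    """Human-readable report of the recomputed benchmark metrics."""
    lines = []
    confusions = reference_confusions()
    for level in _LEVELS:
        for stain in _STAINS:
            cm = confusions[(level, stain)]
            m = metrics_pair(cm)
            lines.append(f"{level} level, {stain.upper()} stain (n={cm.total})")
            lines.append(cm.to_frame().to_string())
            lines.append(
                "4 groups: Accuracy {accuracy_4class}% (kappa {kappa_4class})  |  "
                "Benign vs DCIS: Accuracy {accuracy_2class}% (kappa {kappa_2class})".format(**m)
            )
            lines.append("")
    return "\n".join(lines)
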