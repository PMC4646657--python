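"""Published pixel-level vessel-segmentation scores on the STARE dataset.

Reported evaluations (Se, Sp, Acc, Auc with Auc = (Se+Sp)/2) of the
region-based active-contour family and of classical vessel-segmentation
methods on the 20 STARE fundus images, as printed in the literature.
They are inputs for internal-consistency checks of the summary
statistics (does the printed Auc follow from the printed Se/Sp; do the
printed between-model deltas follow from the rows), not results this
package recomputes from pixels: replicating them requires the STARE
images themselves.
"""

from __future__ import annotations

__all__ = ["STARE_ACTIVE_CONTOURS", "STARE_LITERATURE"]

#: region-based active-contour models evaluated on STARE
STARE_ACTIVE_CONTOURS: dict[str, dict[str, float]] = {
    "cv": {"se": 0.617, "sp": 0.652, "acc": 0.589, "auc": 0.635},
    "lbf": {"se": 0.704, "sp": 0.958, "acc": 0.921, "auc": 0.831},
    "lgdf": {"se": 0.727, "sp": 0.952, "acc": 0.937, "auc": 0.840},
    "mgdf": {"se": 0.758, "sp": 0.965, "acc": 0.952, "auc": 0.862},
}

#: classical (non-active-contour) vessel segmentation methods on STARE
STARE_LITERATURE: dict[str, dict[str, float]] = {
    "you": {"se": 0.726, "sp": 0.975, "acc": 0.949, "auc": 0.851},
    "marin": {"se": 0.694, "sp": 0.981, "acc": 0.952, "auc": 0.838},
    "mendonca": {"se": 0.699, "sp": 0.973, "acc": 0.944, "auc": 0.836},
    "martinez": {"se": 0.750, "sp": 0.956, "acc": 0.941, "auc": 0.853},
    "bankhead": {"se": 0.758, "sp": 0.950, "acc": 0.932, "auc": 0.854},
}
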