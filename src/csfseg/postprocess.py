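"""2.5D slice-consistency postprocessing of predicted CSF masks.

Slice-by-slice 2D inference cannot see the slices above and below, so it
leaves single-slice inconsistencies. One relabelling pass fixes them: a
pixel is added as CSF when both axial neighbours are CSF and it is not, and
removed when both neighbours are background and it is CSF. The pass is pure
(neighbours are always read from the original prediction, making the result
order-independent) and runs exactly once; first and last slices are copied
unchanged.
"""

from __future__ import annotations

import numpy as np

from .volume_io import MaskVolume

__all__ = ["relabel_slice", "postprocess_exam"]


def relabel_slice(below: np.ndarray, current: np.ndarray, above: np.ndarray) -> np.ndarray:
    """Apply the two relabelling rules to one slice given its two neighbours.

    Per pixel: both neighbours CSF and current not → becomes CSF; both
    neighbours background and current CSF → becomes background; any other
    combination is left unchanged.
    """
    below = np.asarray(below)
    current = np.asarray(current)
    above = np.asarray(above)
    if not (below.shape == current.shape == above.shape):
        raise ValueError(
            f"slice shapes differ: below {below.shape}, current {current.shape}, "
            f"above {above.shape}"
        )
    fill = (below == 1) & (above == 1) & (current == 0)
    clear = (below == 0) & (above == 0) & (current == 1)
    out = current.astype(np.uint8).copy()
    out[fill] = 1
    out[clear] = 0
    return out


def postprocess_exam(pred: MaskVolume) -> MaskVolume:
    """Single relabelling pass over a predicted mask volume.

    Every interior slice is relabelled against the ORIGINAL predicted
    neighbours; volumes with two or fewer slices are returned unchanged.
    """
    labels = pred.labels
    if labels.shape[0] <= 2:
        return pred.with_labels(labels.copy())
    out = labels.copy()
    for i in range(1, labels.shape[0] - 1):
        out[i] = relabel_slice(labels[i - 1], labels[i], labels[i + 1])
    return pred.with_labels(out)
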