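"""Named reference fixtures: published direction sets and test tensors.

``koptimal30`` is the published 30-direction K-optimal gradient encoding
scheme for fourth-order tensor estimation and ``koptimal-dti6`` the
6-direction K-optimal scheme for classical (second-order) DTI.  Both are
printed to four decimals, so their points are only approximately unit and
their condition numbers match the theoretical optima (1.9141 and 1.3229)
to the rounding level.

``t01`` .. ``t10`` are the ten fourth-order ground-truth tensors used in
the rotational-variance evaluation, in units of 1e-4 mm^2/s: three
single-fiber profiles (t01-t03), six two-fiber crossings with varying
angle and lobe weights (t04-t09), and one three-perpendicular-fiber
profile (t10).  Coefficients are ordered z^4-slot first, x^4-slot last.
"""

from __future__ import annotations

import numpy as np

from .tensor_model import DirectionSet, TensorCoeffs

__all__ = ["direction_set", "tensor", "direction_names", "tensor_names"]

# 30-direction K-optimal scheme for order-4 estimation (4-decimal points)
_KOPTIMAL30 = np.array([
    [0.1514, -0.9883, -0.0161], [0.3527, -0.8791, 0.3207], [-0.9125, 0.2478, -0.3253],
    [0.4840, 0.1736, -0.8576], [-0.0048, 1.0000, -0.0068], [-0.0163, 0.0245, 0.9996],
    [-0.5357, 0.0645, -0.8419], [0.9960, -0.0292, 0.0842], [0.0160, 0.0349, 0.9993],
    [-0.0633, -0.1941, 0.9789], [0.8959, -0.1044, -0.4317], [0.3204, -0.3626, -0.8751],
    [-0.4457, -0.8893, -0.1024], [-0.0111, 0.0185, 0.9998], [-0.1819, -0.8503, 0.4938],
    [-0.8564, -0.4798, 0.1908], [-0.1289, 0.4227, -0.8970], [0.0248, 0.9996, -0.0146],
    [0.9998, 0.0123, 0.0169], [0.9988, -0.0129, 0.0481], [0.1318, 0.9903, -0.0441],
    [0.8391, -0.5377, -0.0829], [0.0341, 0.9994, -0.0089], [-0.0149, -0.0427, -0.9990],
    [-0.2315, -0.3334, -0.9139], [0.0851, 0.8468, 0.5251], [0.8780, 0.3205, 0.3556],
    [0.3072, -0.9185, -0.2490], [0.9867, 0.0077, -0.1623], [0.9973, 0.0662, -0.0304],
])

# 6-direction K-optimal scheme for second-order DTI
_KOPTIMAL_DTI6 = np.array([
    [0.9096, 0.0000, 0.4155],
    [0.0000, 0.4155, 0.9096],
    [0.4155, 0.9096, 0.0000],
    [0.0000, 0.4155, -0.9096],
    [0.4155, -0.9096, 0.0000],
    [-0.9096, 0.0000, 0.4155],
])

# ten order-4 evaluation tensors, columns t01..t10, rows in the package
# coefficient ordering (z^4 slot first, x^4 slot last); units 1e-4 mm^2/s
_TENSOR_TABLE = np.array([
    #  t01    t02    t03    t04    t05    t06    t07    t08    t09    t10
    [2.00,  0.60,  0.54,  0.73,  0.64,  0.45,  0.69,  0.56,  0.70,  8.50],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [1.00,  0.38,  0.00,  0.00,  0.03,  0.79,  0.29,  0.84,  0.34,  0.00],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [2.00, 13.31, 23.77, 12.51,  8.66,  5.47, 10.86,  7.48,  7.25,  8.50],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [0.00, -1.23,  0.00,  0.00,  0.00,  0.00,  0.13,  0.38, -0.05,  0.00],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [0.00, 30.02,  0.00,  0.00,  0.00,  0.00, 10.37,  6.80, 15.23,  0.00],
    [3.00,  0.99,  2.16,  0.00,  0.00,  0.00,  0.02,  0.04,  0.01,  0.00],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [3.00, 27.03,  0.00,  0.00,  0.00,  0.00,  3.93,  2.32, 12.49,  0.00],
    [0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00],
    [0.00,  9.70,  0.00,  0.00,  0.00,  0.00,  0.69,  0.35,  4.35,  0.00],
    [17.00, 1.83,  0.29, 12.27, 16.20, 19.33, 12.32, 16.18, 13.01,  8.50],
])

_TENSOR_SCALE = 1e-4  # table values are multiples of 1e-4 mm^2/s

_DIRECTION_SETS = {
    "koptimal30": _KOPTIMAL30,
    "koptimal-dti6": _KOPTIMAL_DTI6,
}
_DIRECTION_ALIASES = {
    "table1": "koptimal30",
    "table2": "koptimal-dti6",
}


def direction_names() -> list[str]:
    return sorted(_DIRECTION_SETS)


def tensor_names() -> list[str]:
    return [f"t{i:02d}" for i in range(1, 11)]


def direction_set(name: str) -> DirectionSet:
    """Look up a published direction set by name (printed 4-decimal
    points, hence the loose unit tolerance)."""
    key = _DIRECTION_ALIASES.get(name.lower(), name.lower())
    try:
        pts = _DIRECTION_SETS[key]
    except KeyError:
        raise KeyError(
            f"unknown direction set {name!r}; available: {direction_names()}"
        ) from None
    return DirectionSet(pts, unit_tol=1e-3)


def tensor(name: str) -> TensorCoeffs:
    """Look up an evaluation tensor: ``t01`` .. ``t10`` (``t010`` is
    accepted for the last one)."""
    key = name.lower()
    if key == "t010":
        key = "t10"
    if key.startswith("t") and key[1:].isdigit():
        i = int(key[1:])
        if 1 <= i <= 10:
            return TensorCoeffs(4, _TENSOR_TABLE[:, i - 1] * _TENSOR_SCALE)
    raise KeyError(f"unknown tensor {name!r}; available: {tensor_names()}")
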