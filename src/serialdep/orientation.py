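"""Circular arithmetic for 180°-periodic orientation data.

Orientations of oriented gratings are defined on [0, 180): a Gabor at 10°
is indistinguishable from one at 190°.  Signed differences therefore live
on (−90, 90].  The +90 boundary is assigned positive sign by convention,
so ``wrap_diff(a, b)`` and ``-wrap_diff(b, a)`` agree everywhere except at
exactly 90° apart, where both return +90.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_diff", "wrap_orientation"]


def wrap_orientation(theta):
    """Map angles (degrees) into the orientation domain [0, 180)."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("orientations must be finite")
    out = np.mod(theta, 180.0)
    return out if out.ndim else float(out)


def wrap_diff(a, b):
    """Signed acute difference ``a − b`` in degrees, wrapped into (−90, 90].

    Works elementwise on arrays.  NaN inputs raise; use masking upstream
    for optional quantities (e.g. trials without a distractor).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("wrap_diff requires finite inputs")
    d = np.mod(a - b, 180.0)
    out = np.where(d > 90.0, d - 180.0, d)
    return out if out.ndim else float(out)
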