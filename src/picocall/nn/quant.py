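"""Uniform symmetric fake quantization.

Values are quantized to ``2**bits - 1`` integer levels spanning
``[-max|v|, +max|v|]`` and immediately dequantized, so the forward pass sees
the rounding error a low-precision deployment would see while arithmetic stays
in floating point.  Gradients use the straight-through estimator: because the
quantization range always covers the data, the STE is exactly the identity and
no layer needs a dedicated backward pass for it.
"""

from __future__ import annotations

import numpy as np

#: Bit-widths accepted throughout the package; 32 means "leave in fp32".
ALLOWED_BITS = (4, 8, 16, 32)


def fake_quantize(values: np.ndarray, bits: int) -> np.ndarray:
    """Quantize-dequantize ``values`` to a symmetric ``bits``-wide grid.

    ``bits=32`` is the identity.  The grid has ``2**bits - 1`` levels (integer
    codes ``-(2**(bits-1)-1) .. +(2**(bits-1)-1)``), scaled so the largest
    magnitude in ``values`` sits exactly on the endpoint; an all-zero tensor is
    returned unchanged.

    Raises
    ------
    ValueError
        If ``bits`` is not one of 4, 8, 16, 32 or the input is non-finite.
    """
    if bits not in ALLOWED_BITS:
        raise ValueError(f"bits must be one of {ALLOWED_BITS}, got {bits}")
    values = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("fake_quantize requires finite input values")
    if bits >= 32:
        return values.copy()
    vmax = np.max(np.abs(values))
    if vmax == 0.0:
        return values.copy()
    qmax = 2 ** (bits - 1) - 1
    scale = vmax / qmax
    return np.round(values / scale) * scale
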