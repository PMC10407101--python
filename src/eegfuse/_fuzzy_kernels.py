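"""Compiled inner loops for fuzzy entropy.

The kernels fill packed upper-triangle Chebyshev distance arrays between
baseline-removed templates of length ``m`` and ``m + 1`` (both lengths share
the same N - m template positions).  The exponential similarity kernel and
the averaging are applied by the caller with vectorized numpy, which is
faster than scalar ``exp`` calls inside the loop.

A specialized kernel covers the default template length m = 2; a generic
kernel handles any m.  Both preserve the input dtype.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(fastmath=True, cache=True)
def chebyshev_pairs_m2(x, d_m, d_m1):  # pragma: no cover - compiled
    n_templates = x.size - 2
    y20 = np.empty(n_templates, x.dtype)
    y21 = np.empty(n_templates, x.dtype)
    y30 = np.empty(n_templates, x.dtype)
    y31 = np.empty(n_templates, x.dtype)
    y32 = np.empty(n_templates, x.dtype)
    for i in range(n_templates):
        b2 = (x[i] + x[i + 1]) / 2
        b3 = (x[i] + x[i + 1] + x[i + 2]) / 3
        y20[i] = x[i] - b2
        y21[i] = x[i + 1] - b2
        y30[i] = x[i] - b3
        y31[i] = x[i + 1] - b3
        y32[i] = x[i + 2] - b3
    idx = 0
    for i in range(n_templates):
        a0 = y20[i]
        a1 = y21[i]
        c0 = y30[i]
        c1 = y31[i]
        c2 = y32[i]
        for j in range(i + 1, n_templates):
            d0 = abs(a0 - y20[j])
            d1 = abs(a1 - y21[j])
            d_m[idx + j - i - 1] = d0 if d0 > d1 else d1
            e0 = abs(c0 - y30[j])
            e1 = abs(c1 - y31[j])
            e2 = abs(c2 - y32[j])
            if e1 > e0:
                e0 = e1
            if e2 > e0:
                e0 = e2
            d_m1[idx + j - i - 1] = e0
        idx += n_templates - i - 1


@njit(fastmath=True, cache=True)
def chebyshev_pairs_generic(x, m, d_m, d_m1):  # pragma: no cover - compiled
    n_templates = x.size - m
    b_m = np.empty(n_templates, x.dtype)
    b_m1 = np.empty(n_templates, x.dtype)
    for i in range(n_templates):
        s = x.dtype.type(0.0)
        for k in range(m):
            s += x[i + k]
        b_m[i] = s / m
        s += x[i + m]
        b_m1[i] = s / (m + 1)
    idx = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            d = x.dtype.type(0.0)
            for k in range(m):
                diff = abs((x[i + k] - b_m[i]) - (x[j + k] - b_m[j]))
                if diff > d:
                    d = diff
            d_m[idx] = d
            d = x.dtype.type(0.0)
            for k in range(m + 1):
                diff = abs((x[i + k] - b_m1[i]) - (x[j + k] - b_m1[j]))
                if diff > d:
                    d = diff
            d_m1[idx] = d
            idx += 1
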