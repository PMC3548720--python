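"""Independent arbitrary-precision oracles for the closed-form quantities.

Everything here is computed with mpmath at 40 significant digits,
straight from the defining formulas, with none of the series expansions
or log-space rearrangements the package uses — so agreement is evidence,
not tautology.
"""

import mpmath as mp

mp.mp.dps = 150  # tiny-t survival values need far more than double precision


def mp_w(t, alpha, beta):
    t, alpha, beta = mp.mpf(str(t)), mp.mpf(str(alpha)), mp.mpf(str(beta))
    x = t ** beta
    return alpha * (1 - x * mp.coth(x)) / beta


def mp_sf(t, alpha, beta):
    return mp.sech(mp_w(t, alpha, beta))


def mp_cdf(t, alpha, beta):
    return 1 - mp_sf(t, alpha, beta)


def mp_hazard(t, alpha, beta):
    t, alpha, beta = mp.mpf(str(t)), mp.mpf(str(alpha)), mp.mpf(str(beta))
    x = t ** beta
    w = alpha * (1 - x * mp.coth(x)) / beta
    bracket = t ** (2 * beta - 1) * mp.csch(x) ** 2 - t ** (beta - 1) * mp.coth(x)
    return alpha * bracket * mp.tanh(w)


def mp_pdf(t, alpha, beta):
    return mp_hazard(t, alpha, beta) * mp_sf(t, alpha, beta)


def rel_err(value, reference) -> float:
    reference = float(reference)
    if reference == 0.0:
        return abs(float(value))
    return abs(float(value) - reference) / abs(reference)
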