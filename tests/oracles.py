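"""Independent oracle implementations used only by the tests.

Each oracle is coded from first principles, separately from the package's
closed forms, so that agreement is a genuine dual-route check:

- ``singlek_srkt_refraction`` / ``singlek_srkt_emmetropia_power``: classical
  single-K SRK/T, written step by step with its own variable flow.
- ``physical_refraction``: the predicted refraction obtained not from the
  closed form but by root-finding on the physical vergence chain (a thin
  spectacle lens, a single refracting cornea, a thin IOL, image on the
  retina).
- ``brute_wilcoxon_p``: the exact two-sided signed-rank p by enumerating
  all sign assignments.
- ``brute_fisher_p``: the conventional two-sided Fisher p as a
  hypergeometric sum over tables at most as probable as the observed one.
- ``naive_summary``: spreadsheet-style error statistics with plain Python
  loops.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np
from scipy.optimize import brentq
from scipy.stats import hypergeom, rankdata

NA, NC, V = 1.336, 1.333, 12.0


def _srkt_acd(k_d: float, L: float, a_constant: float) -> float:
    r = 337.5 / k_d
    lcor = L if L <= 24.2 else -3.446 + 1.715 * L - 0.0237 * L * L
    cw = -5.41 + 0.58412 * lcor + 0.098 * k_d
    h = r - math.sqrt(max(0.0, r * r - cw * cw / 4.0))
    return h + (0.62467 * a_constant - 68.747) - 3.336


def singlek_srkt_refraction(L, k_d, a_constant, lens_power):
    """Classical single-K SRK/T predicted refraction (one K for both ELP
    and vergence)."""
    r = 337.5 / k_d
    lopt = L + 0.65696 - 0.02029 * L
    acd = _srkt_acd(k_d, L, a_constant)
    n1 = 1000.0 * NA * (NA * r - (NC - 1.0) * lopt)
    t_acd = NA * r - (NC - 1.0) * acd
    num = n1 - lens_power * (lopt - acd) * t_acd
    den = NA * (V * (NA * r - (NC - 1.0) * lopt) + lopt * r) - 0.001 * lens_power * (
        lopt - acd
    ) * (V * t_acd + acd * r)
    return num / den


def singlek_srkt_emmetropia_power(L, k_d, a_constant):
    """Classical single-K SRK/T IOL power for emmetropia."""
    r = 337.5 / k_d
    lopt = L + 0.65696 - 0.02029 * L
    acd = _srkt_acd(k_d, L, a_constant)
    return (1000.0 * NA * (NA * r - (NC - 1.0) * lopt)) / (
        (lopt - acd) * (NA * r - (NC - 1.0) * acd)
    )


def physical_refraction(L, kpost, kpre, a_constant, lens_power):
    """Spectacle refraction solved from the physical vergence chain.

    Finds REF such that a ray bundle from the far point of a REF-diopter
    spectacle at 12 mm vertex, refracted by a cornea of power
    1000*(nc-1)/rpost and a thin IOL at the double-K ELP, images exactly on
    the retina at the adjusted axial length.
    """
    r = 337.5 / kpost
    lopt = L + 0.65696 - 0.02029 * L
    acd = _srkt_acd(kpre, L, a_constant)
    k_cornea = 1000.0 * (NC - 1.0) / r

    def image_position(ref):
        if ref == 0.0:
            v_at_cornea = 0.0
        else:
            far_point_mm = 1000.0 / ref
            v_at_cornea = 1000.0 / (far_point_mm - V)
        v_after_cornea = v_at_cornea + k_cornea
        if v_after_cornea == 0.0:
            reduced = -acd / 1000.0
        else:
            reduced = NA / v_after_cornea - acd / 1000.0
        v_at_iol = NA / reduced
        v_after_iol = v_at_iol + lens_power
        return acd + NA / v_after_iol * 1000.0

    return brentq(lambda ref: image_position(ref) - lopt, -45.0, 45.0, xtol=1e-13)


def brute_wilcoxon_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign flips
    (zero differences dropped; requires tie-free |diffs|)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [ranks[np.array(signs, bool)].sum()
         for signs in itertools.product([0, 1], repeat=d.size)]
    )
    return min(1.0, 2.0 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))


def brute_fisher_p(a, b, c, d):
    """Two-sided Fisher p: hypergeometric sum over tables with probability
    at most that of the observed table (fixed margins)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    pmfs = rv.pmf(ks)
    return float(pmfs[pmfs <= p_obs * (1.0 + 1e-7)].sum())


def naive_summary(errors):
    """Spreadsheet-style recomputation of the outcome statistics."""
    errors = list(float(e) for e in errors)
    n = len(errors)
    abs_err = [abs(e) for e in errors]
    return {
        "n": n,
        "mean_numerical_d": sum(errors) / n,
        "sd_numerical_d": statistics.stdev(errors) if n > 1 else 0.0,
        "mean_absolute_d": sum(abs_err) / n,
        "sd_absolute_d": statistics.stdev(abs_err) if n > 1 else 0.0,
        "median_absolute_d": statistics.median(abs_err),
        "pct_within_025": 100.0 * sum(e <= 0.25 for e in abs_err) / n,
        "pct_within_050": 100.0 * sum(e <= 0.50 for e in abs_err) / n,
        "pct_within_100": 100.0 * sum(e <= 1.00 for e in abs_err) / n,
    }
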