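"""Numba-compiled batch likelihoods used by the hierarchical sampler.

These duplicate the pure-Python likelihoods in :mod:`setshift.models` for
speed (the sampler evaluates them tens of thousands of times); agreement
between the two routes is asserted in the test suite.

Data layout: subjects are padded to a common trial count ``T``; ``n_trials``
gives each subject's true length.  PRL choices are coded 0 (A) / 1 (B);
WCST choices 0..3; WCST card/deck match structure is passed as a bitmask per
(subject, trial, deck) with bit 0 = color, bit 1 = shape, bit 2 = number.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH_EPS = 1e-6  # keep in sync with setshift.models.MATCH_EPS


@njit(cache=True)
def prl_loglik_batch(choices, outcomes, n_trials, params):
    """Log-likelihood per subject of the 4-parameter PRL model.

    choices, outcomes : int8[S, T];  n_trials : int64[S]
    params : float64[S, 4]  columns (alpha_rew, alpha_pun, beta, kappa)
    """
    S = choices.shape[0]
    out = np.empty(S)
    for s in range(S):
        a_rew = params[s, 0]
        a_pun = params[s, 1]
        beta = params[s, 2]
        kappa = params[s, 3]
        qa = 0.5
        qb = 0.5
        prev = -1
        ll = 0.0
        for t in range(n_trials[s]):
            la = beta * qa
            lb = beta * qb
            if prev == 0:
                la += kappa
            elif prev == 1:
                lb += kappa
            m = la if la > lb else lb
            lse = m + np.log(np.exp(la - m) + np.exp(lb - m))
            c = choices[s, t]
            ll += (la if c == 0 else lb) - lse
            o = outcomes[s, t]
            rate = a_rew if o == 1 else a_pun
            if c == 0:
                qa = qa + rate * (o - qa)
            else:
                qb = qb + rate * (o - qb)
            prev = c
        out[s] = ll
    return out


@njit(cache=True)
def wcst_loglik_batch(match_bits, choices, feedback, n_trials, params):
    """Log-likelihood per subject of the 3-parameter WCST attention model.

    match_bits : uint8[S, T, 4];  choices, feedback : int8[S, T]
    params : float64[S, 3]  columns (r, p, d)
    """
    S = choices.shape[0]
    out = np.empty(S)
    att = np.empty(3)
    m = np.empty(4)
    logw = np.empty(4)
    target = np.empty(3)
    for s in range(S):
        r = params[s, 0]
        p = params[s, 1]
        d = params[s, 2]
        att[0] = 1.0 / 3.0
        att[1] = 1.0 / 3.0
        att[2] = 1.0 / 3.0
        ll = 0.0
        for t in range(n_trials[s]):
            for k in range(4):
                bits = match_bits[s, t, k]
                sig = 0.0
                for dim in range(3):
                    if bits & (1 << dim):
                        sig += att[dim]
                if sig < MATCH_EPS:
                    sig = MATCH_EPS
                m[k] = sig
            mx = -1e300
            for k in range(4):
                logw[k] = d * np.log(m[k])
                if logw[k] > mx:
                    mx = logw[k]
            tot = 0.0
            for k in range(4):
                tot += np.exp(logw[k] - mx)
            lse = mx + np.log(tot)
            c = choices[s, t]
            ll += logw[c] - lse

            fb = feedback[s, t]
            bits = match_bits[s, t, c]
            if fb == 0:
                bits = (~bits) & 0b111
            if bits != 0:
                mass = 0.0
                nset = 0
                for dim in range(3):
                    if bits & (1 << dim):
                        mass += att[dim]
                        nset += 1
                for dim in range(3):
                    if bits & (1 << dim):
                        target[dim] = att[dim] / mass if mass >= 1e-12 else 1.0 / nset
                    else:
                        target[dim] = 0.0
                lam = r if fb == 1 else p
                tot = 0.0
                for dim in range(3):
                    att[dim] = (1.0 - lam) * att[dim] + lam * target[dim]
                    tot += att[dim]
                for dim in range(3):
                    att[dim] /= tot
        out[s] = ll
    return out
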