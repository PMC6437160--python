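"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities from first principles (direct
enumeration, closed forms) rather than reusing the package's algorithms.
"""

import numpy as np

from globinchar.genetics.linkage import (
    _haplotype_prior,
    _observation,
    _transmission,
)


def brute_force_likelihood(ped, model, marker_freqs, theta: float) -> float:
    """Pedigree likelihood by direct summation over all joint ordered
    two-locus genotype states (numpy broadcasting; feasible to ~6 members
    with a biallelic marker)."""
    freqs = np.asarray(marker_freqs, dtype=float)
    k = freqs.size
    G = 2 * k
    S = G * G
    T = _transmission(theta, k)
    prior_s = np.kron(_haplotype_prior(model, freqs), _haplotype_prior(model, freqs))
    obs = _observation(ped, model, k)
    n = len(ped.members)
    idx = {m.id: i for i, m in enumerate(ped.members)}
    joint = np.ones((S,) * n)

    def reshape_for(i, vec):
        shape = [1] * n
        shape[i] = S
        return vec.reshape(shape)

    for m in ped.members:
        i = idx[m.id]
        joint *= reshape_for(i, obs[m.id])
        if m.is_founder:
            joint *= reshape_for(i, prior_s)
        else:
            fi, mi = idx[m.father], idx[m.mother]
            # T2[state_father, state_mother, state_child]
            T2 = np.einsum("fa,mb->fmab", T, T).reshape(S, S, S)
            pos = sorted([(fi, 0), (mi, 1), (i, 2)])
            perm = [p[1] for p in pos]
            shape = [1] * n
            shape[fi] = shape[mi] = shape[i] = S
            joint *= np.transpose(T2, perm).reshape(shape)
    return float(joint.sum())


def weighted_line_fit(x, y, w):
    """Textbook closed-form weighted least squares for y = a + b x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    b = (w * (x - xbar) * (y - ybar)).sum() / sxx
    a = ybar - b * xbar
    return a, b
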