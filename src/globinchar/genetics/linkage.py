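"""Single-marker parametric LOD scores by Elston-Stewart peeling.

The disease locus is biallelic with a penetrance vector over disease-allele
dosage; the marker carries an arbitrary allele-frequency vector.  Founders
are at Hardy-Weinberg and linkage equilibrium; transmissions recombine at
fraction theta.  Peeling is exact for loop-free pedigrees and equals a
brute-force sum over joint two-locus genotypes (verified in the test
suite).  LOD(theta) = log10 L(theta) - log10 L(0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, Pedigree


@dataclass(frozen=True)
class DiseaseModel:
    """Dominant single-locus model: P(affected | dosage of disease allele)."""

    disease_allele_freq: float = 0.001
    penetrances: tuple[float, float, float] = (0.001, 0.999, 0.999)

    def __post_init__(self) -> None:
        if not (0.0 < self.disease_allele_freq < 1.0):
            raise ValueError("disease allele frequency must be in (0, 1)")
        if any(not (0.0 <= p <= 1.0) for p in self.penetrances):
            raise ValueError("penetrances must be probabilities")


FULLY_PENETRANT_DOMINANT = DiseaseModel(
    disease_allele_freq=0.001, penetrances=(0.0, 1.0, 1.0)
)


def _haplotype_prior(model: DiseaseModel, marker_freqs: np.ndarray) -> np.ndarray:
    q = model.disease_allele_freq
    pd = np.array([1.0 - q, q])
    return np.kron(pd, marker_freqs)  # h = d * k + m


def _transmission(theta: float, k: int) -> np.ndarray:
    """T[s, g]: P(gamete haplotype g | parent ordered-haplotype state s)."""
    G = 2 * k
    T = np.zeros((G * G, G))
    for hp in range(G):
        for hm in range(G):
            s = hp * G + hm
            dp, mp = divmod(hp, k)
            dm, mm = divmod(hm, k)
            for dd, mg, w in (
                (dp, mp, 0.5 * (1.0 - theta)),
                (dp, mm, 0.5 * theta),
                (dm, mp, 0.5 * theta),
                (dm, mm, 0.5 * (1.0 - theta)),
            ):
                T[s, dd * k + mg] += w
    return T


def _observation(ped: Pedigree, model: DiseaseModel, k: int) -> dict[str, np.ndarray]:
    """Per-person vector over ordered states: penetrance x marker match."""
    G = 2 * k
    S = G * G
    pen = np.asarray(model.penetrances)
    obs = {}
    dosage = np.empty(S, dtype=int)
    pat_m = np.empty(S, dtype=int)
    mat_m = np.empty(S, dtype=int)
    for hp in range(G):
        for hm in range(G):
            s = hp * G + hm
            dosage[s] = hp // k + hm // k
            pat_m[s] = hp % k
            mat_m[s] = hm % k
    for m in ped.members:
        v = np.ones(S)
        if m.affected == AFFECTED:
            v *= pen[dosage]
        elif m.affected == UNAFFECTED:
            v *= 1.0 - pen[dosage]
        if m.genotype is not None:
            a = m.genotype[0] - 1
            b = m.genotype[1] - 1
            if not (0 <= a < k and 0 <= b < k):
                raise ValueError(f"{m.id}: marker allele outside frequency vector")
            match = ((pat_m == a) & (mat_m == b)) | ((pat_m == b) & (mat_m == a))
            v *= match.astype(float)
        obs[m.id] = v
    return obs


class _Peeler:
    """Anterior/posterior peeling over ordered two-locus states."""

    def __init__(self, ped: Pedigree, model: DiseaseModel,
                 marker_freqs: np.ndarray, theta: float):
        self.ped = ped
        k = marker_freqs.size
        self.G = 2 * k
        self.T = _transmission(theta, k)
        self.prior = np.kron(_haplotype_prior(model, marker_freqs),
                             _haplotype_prior(model, marker_freqs))
        self.obs = _observation(ped, model, k)
        self.couples: dict[tuple[str, str], list[str]] = {}
        self.spouses: dict[str, list[str]] = {m.id: [] for m in ped.members}
        for m in ped.members:
            if m.is_founder:
                continue
            key = (m.father, m.mother)
            self.couples.setdefault(key, []).append(m.id)
        for fa, mo in self.couples:
            self.spouses[fa].append(mo)
            self.spouses[mo].append(fa)
        self._ant: dict[str, np.ndarray] = {}
        self._post: dict[tuple[str, str], np.ndarray] = {}

    def _child_matrix(self, child_id: str) -> np.ndarray:
        """M[x_father, y_mother] summing the child's downward branch."""
        w = self.obs[child_id].copy()
        for s in self.spouses[child_id]:
            w = w * self.posterior(child_id, s)
        W = w.reshape(self.G, self.G)
        return self.T @ W @ self.T.T

    def anterior(self, iid: str) -> np.ndarray:
        if iid in self._ant:
            return self._ant[iid]
        person = self.ped.by_id[iid]
        if person.is_founder:
            out = self.prior
        else:
            fa, mo = person.father, person.mother
            afv = self.anterior(fa) * self.obs[fa]
            for s in self.spouses[fa]:
                if s != mo:
                    afv = afv * self.posterior(fa, s)
            amv = self.anterior(mo) * self.obs[mo]
            for s in self.spouses[mo]:
                if s != fa:
                    amv = amv * self.posterior(mo, s)
            U = afv[:, None] * amv[None, :]
            for sib in self.couples[(fa, mo)]:
                if sib != iid:
                    U = U * self._child_matrix(sib)
            out = (self.T.T @ U @ self.T).reshape(-1)
        self._ant[iid] = out
        return out

    def posterior(self, iid: str, spouse: str) -> np.ndarray:
        key = (iid, spouse)
        if key in self._post:
            return self._post[key]
        sv = self.anterior(spouse) * self.obs[spouse]
        for t in self.spouses[spouse]:
            if t != iid:
                sv = sv * self.posterior(spouse, t)
        if (iid, spouse) in self.couples:
            kids, i_is_father = self.couples[(iid, spouse)], True
        else:
            kids, i_is_father = self.couples[(spouse, iid)], False
        K = np.ones((self.prior.size, self.prior.size))
        for c in kids:
            K = K * (self._child_matrix(c) if i_is_father
                     else self._child_matrix(c).T)
        out = K @ sv
        self._post[key] = out
        return out

    def likelihood(self) -> float:
        anchor = self.ped.members[0].id
        v = self.anterior(anchor) * self.obs[anchor]
        for s in self.spouses[anchor]:
            v = v * self.posterior(anchor, s)
        return float(v.sum())


def pedigree_likelihood(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta: float,
) -> float:
    """Exact likelihood of the pedigree's phenotype + marker data."""
    freqs = np.asarray(marker_freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size < 2 or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("marker allele frequencies must sum to 1 (>= 2 alleles)")
    if not (0.0 <= theta <= 0.5):
        raise ValueError("theta must lie in [0, 0.5]")
    if ped.has_loops():
        raise ValueError("looped pedigrees are not supported")
    ped.check_mendelian()
    return _Peeler(ped, model, freqs, theta).likelihood()


def lod_single_marker(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta: float,
) -> float:
    """LOD(theta) = log10 [ L(theta) / L(0.5) ]; exactly 0 at theta = 0.5."""
    if theta == 0.5:
        return 0.0
    L_theta = pedigree_likelihood(ped, model, marker_freqs, theta)
    L_null = pedigree_likelihood(ped, model, marker_freqs, 0.5)
    if L_null <= 0.0:
        raise ValueError("pedigree data have zero likelihood under the model")
    if L_theta <= 0.0:
        return -np.inf
    return float(np.log10(L_theta) - np.log10(L_null))


def max_lod(
    ped: Pedigree,
    model: DiseaseModel,
    marker_freqs,
    theta_grid=None,
) -> tuple[float, float]:
    """Grid maximum of LOD(theta); ties break toward smaller theta."""
    grid = np.arange(0.0, 0.5001, 0.01) if theta_grid is None else np.asarray(theta_grid)
    lods = np.array([lod_single_marker(ped, model, marker_freqs, t) for t in grid])
    i = int(np.argmax(lods))  # first max -> smallest theta on ascending grid
    return float(grid[i]), float(lods[i])
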