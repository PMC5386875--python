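"""Goldman–Yang codon substitution model: generator, transition matrices,
site counts and substitution partitioning.

The instantaneous rate from codon *i* to codon *j* is zero unless the codons
differ at exactly one position; single-step rates are

    q_ij = pi_j            synonymous transversion
         = kappa pi_j      synonymous transition
         = omega pi_j      nonsynonymous transversion
         = omega kappa pi_j  nonsynonymous transition

with the diagonal closing rows to zero.  Generators are scaled so the
expected equilibrium rate is one substitution per codon per unit branch
length; when site classes mix several omegas on one branch the class
generators share a single mixture-weighted scale (see likelihood module).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_code import (
    CODON_INDEX,
    N_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
    single_step_changes,
)

__all__ = [
    "CodonModelSpec",
    "build_rate_matrix",
    "EigenSystem",
    "flux_fractions",
    "count_sites",
    "split_substitutions",
    "f3x4_frequencies",
    "uniform_frequencies",
]

# index arrays over ordered single-nucleotide codon pairs
_CH = single_step_changes()
_I = np.array([c[0] for c in _CH])
_J = np.array([c[1] for c in _CH])
_TS = np.array([c[2] for c in _CH])
_SYN = np.array([c[3] for c in _CH])


def uniform_frequencies() -> np.ndarray:
    """Equal frequency on each of the 61 sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(alignments, pseudocount: float = 1.0) -> np.ndarray:
    """F3x4 codon frequencies from observed position-specific composition.

    Nucleotide frequencies are tallied separately at the three codon
    positions over every ungapped, unambiguous codon of every sequence;
    codon frequencies are the per-position products renormalised over the
    61 sense codons.  A small pseudocount keeps frequencies strictly
    positive on short genes.
    """
    if not isinstance(alignments, (list, tuple)):
        alignments = [alignments]
    counts = np.full((3, 4), float(pseudocount))
    nt_idx = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for aln in alignments:
        for seq in aln.sequences:
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3]
                if codon in CODON_INDEX:
                    for pos, n in enumerate(codon):
                        counts[pos, nt_idx[n]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_idx[c[0]]] * freqs[1, nt_idx[c[1]]] * freqs[2, nt_idx[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


@dataclass
class CodonModelSpec:
    """Model settings shared across branches: kappa and codon frequencies.

    ``frequency_mode`` records provenance only ("uniform" or "F3x4"); the
    61-vector ``codon_freqs`` is what enters the generator.
    """

    kappa: float = 2.0
    codon_freqs: np.ndarray = field(default_factory=uniform_frequencies)
    frequency_mode: str = "uniform"

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        pi = self.codon_freqs
        if pi.shape != (N_CODONS,):
            raise ValueError(f"codon_freqs must have {N_CODONS} entries")
        if (pi < 0).any():
            raise ValueError("codon_freqs must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(f"codon_freqs must sum to 1 (sum={pi.sum()!r})")

    @classmethod
    def f3x4(cls, alignments, kappa: float = 2.0) -> "CodonModelSpec":
        return cls(
            kappa=kappa,
            codon_freqs=f3x4_frequencies(alignments),
            frequency_mode="F3x4",
        )

    def with_kappa(self, kappa: float) -> "CodonModelSpec":
        return CodonModelSpec(kappa, self.codon_freqs, self.frequency_mode)


def build_rate_matrix(
    spec: CodonModelSpec, omega: float, scale: bool = True
) -> np.ndarray:
    """61x61 generator for the given omega; reversible w.r.t. codon_freqs.

    With ``scale=True`` the generator is normalised to one expected
    substitution per codon at equilibrium.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    spec.validate()
    pi = spec.codon_freqs
    rates = pi[_J] * np.where(_TS, spec.kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_I, _J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        r = expected_rate(Q, pi)
        if r > 0:
            Q /= r
    return Q


def expected_rate(Q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time at equilibrium."""
    return float(-(pi * np.diag(Q)).sum())


class EigenSystem:
    """Spectral form of a reversible generator for fast ``exp(Q t)``.

    The similarity transform ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is
    symmetric for reversible Q; one ``eigh`` then yields transition matrices
    for any t by rescaling eigenvalue exponentials.
    """

    __slots__ = ("w", "left", "right", "rate")

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self.w = w
        self.left = V / sqrt_pi[:, None]
        self.right = (V * sqrt_pi[:, None]).T
        self.rate = expected_rate(Q, pi)

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to one, entries clipped at zero."""
        if t < 0:
            raise ValueError(f"negative time {t}")
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


def flux_fractions(spec: CodonModelSpec, omega: float) -> tuple[float, float]:
    """Fractions of equilibrium substitution flux that are (nonsyn, syn)."""
    pi = spec.codon_freqs
    rates = pi[_I] * pi[_J] * np.where(_TS, spec.kappa, 1.0)
    nonsyn = omega * rates[~_SYN].sum()
    syn = rates[_SYN].sum()
    total = nonsyn + syn
    if total == 0:
        return 0.0, 0.0
    return nonsyn / total, syn / total


def count_sites(kappa: float, codon_usage) -> tuple[float, float]:
    """Per-codon mutational-opportunity site counts (N, S), usage-averaged.

    For each codon, every single-nucleotide change to another sense codon is
    weighted kappa (transition) or 1 (transversion); changes to stop codons
    are excluded.  S per codon is 3 x the weighted synonymous fraction and
    N = 3 - S; the gene-level counts average over the supplied codon usage
    (mapping codon -> count or 61-vector) and satisfy N + S = 3 x total.

    The single-codon oracle: TTT at kappa=1 has 1 synonymous change among
    its 9, so S = 1/3.
    """
    if isinstance(codon_usage, dict):
        usage = np.zeros(N_CODONS)
        for codon, n in codon_usage.items():
            usage[CODON_INDEX[codon]] += n
    else:
        usage = np.asarray(codon_usage, dtype=float)
    weights = np.where(_TS, kappa, 1.0)
    syn_w = np.bincount(_I, weights=weights * _SYN, minlength=N_CODONS)
    tot_w = np.bincount(_I, weights=weights, minlength=N_CODONS)
    s_per_codon = 3.0 * np.divide(
        syn_w, tot_w, out=np.zeros(N_CODONS), where=tot_w > 0
    )
    total = usage.sum()
    if total == 0:
        raise ValueError("empty codon usage")
    S = float((usage * s_per_codon).sum())
    N = 3.0 * total - S
    return N, S


def split_substitutions(
    spec: CodonModelSpec, omega: float, t: float, n_codons: int
) -> dict[str, float]:
    """Partition a branch's expected substitutions into dN and dS.

    The branch length t (substitutions per codon) is split by the
    equilibrium flux fractions of the fitted generator; per-site rates are
    normalised by model-based mutational opportunities N = 3L * rhoN and
    S = 3L * rhoS where (rhoN, rhoS) are the neutral (omega=1) flux
    fractions under the same kappa and pi.  Under this normalisation
    dN/dS == omega identically.

    Returns a dict with keys nN, nS (expected substitution counts), N, S
    (site opportunities), dN, dS, and dNdS (NaN when dS == 0).
    """
    if t < 0 or n_codons <= 0:
        raise ValueError("need t >= 0 and n_codons > 0")
    fN, fS = flux_fractions(spec, omega)
    rhoN, rhoS = flux_fractions(spec, 1.0)
    L = float(n_codons)
    nN, nS = t * fN * L, t * fS * L
    N, S = 3.0 * L * rhoN, 3.0 * L * rhoS
    dN = nN / N if N > 0 else 0.0
    dS = nS / S if S > 0 else 0.0
    return {
        "nN": nN,
        "nS": nS,
        "N": N,
        "S": S,
        "dN": dN,
        "dS": dS,
        "dNdS": dN / dS if dS > 0 else float("nan"),
    }
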