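"""Model parameters for the posterior stage.

Two probabilistic models produce the pairwise posterior matrices:

* a 5-state pair hidden Markov model (match state plus short/long insert
  state pairs) in the ProbCons family, with a joint match-emission
  distribution derived from a log-odds substitution matrix and background
  residue frequencies;
* a partition function over affine-gap global alignments, Boltzmann-weighted
  with inverse temperature ``beta`` over a substitution score table
  (Gonnet-style by default).

Neither model is trained here; defaults follow the conventional operating
points of the ProbCons/Probalign lineage and every number can be overridden
through a plain-text ``key = value`` parameter file (see :func:`load_params`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import AMINO, NUCLEOTIDE

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
NT_ORDER = "ACGT"

# BLOSUM62 background amino-acid frequencies (order AA_ORDER).
_AA_BACKGROUND = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}
_WILDCARD_FREQ = 0.005  # mass given to the wildcard (X / N) letter

# 5-state pair-HMM transition magnitudes (ProbCons-family conventions):
# short-gap open/extend and long-gap open/extend, plus the initial state
# distribution.  States are ordered (M, Xshort, Yshort, Xlong, Ylong).
_HMM_DEFAULTS = {
    "hmm_gap_open_short": 0.0119511066,
    "hmm_gap_extend_short": 0.3965826333,
    "hmm_gap_open_long": 0.008008334786,
    "hmm_gap_extend_long": 0.8988758326,
}
_HMM_PI = (0.6814756989, 8.615339902e-05, 8.615339902e-05,
           0.1591759026, 0.1591759026)

N_STATES = 5


def alphabet_order(alphabet: str) -> str:
    return AA_ORDER if alphabet == AMINO else NT_ORDER


def wildcard_index(alphabet: str) -> int:
    return len(alphabet_order(alphabet))


def encode(seq: str, alphabet: str) -> np.ndarray:
    """Encode residues as small integers; ambiguity codes map to the wildcard."""
    order = alphabet_order(alphabet)
    lut = np.full(128, len(order), dtype=np.int8)
    for i, ch in enumerate(order):
        lut[ord(ch)] = i
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[codes].astype(np.int64)


def _background(alphabet: str) -> np.ndarray:
    order = alphabet_order(alphabet)
    if alphabet == AMINO:
        q = np.array([_AA_BACKGROUND[a] for a in order], dtype=float)
    else:
        q = np.full(len(order), 0.25)
    q = q / q.sum() * (1.0 - _WILDCARD_FREQ)
    return np.append(q, _WILDCARD_FREQ)


def _joint_from_matrix(name: str, alphabet: str) -> np.ndarray:
    """Joint residue-pair distribution q_a q_b 2^(s/2), wildcard at odds 1.

    The half-bit convention matches BLOSUM-style log-odds tables; the exact
    exponent base only shifts the implied evolutionary distance of the match
    state, which is a free modelling choice here.
    """
    order = alphabet_order(alphabet)
    k = len(order)
    q = _background(alphabet)
    mat = substitution_matrices.load(name)
    joint = np.empty((k + 1, k + 1))
    # wildcard rows/cols at odds ratio 1 (no information)
    joint[:, :] = np.outer(q, q)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            joint[i, j] = q[i] * q[j] * 2.0 ** (mat[a, b] / 2.0)
    joint /= joint.sum()
    return joint


def _nt_joint() -> np.ndarray:
    """Identity-biased joint for nucleotides (~88% expected identity)."""
    k = 4
    q = _background(NUCLEOTIDE)
    joint = np.outer(q, q)
    for i in range(k):
        for j in range(k):
            joint[i, j] = 0.22 if i == j else 0.01
    joint /= joint.sum()
    return joint


@dataclass(frozen=True)
class HmmParams:
    """5-state pair-HMM: initial/transition probabilities and emissions."""

    pi: np.ndarray            # (5,) initial state distribution
    trans: np.ndarray         # (5, 5) row-stochastic transition matrix
    match_emit: np.ndarray    # (K+1, K+1) joint pair emission, sums to 1
    ins_emit: np.ndarray      # (K+1,) single-residue emission, sums to 1
    alphabet: str = AMINO

    def __post_init__(self):
        if self.pi.shape != (N_STATES,) or self.trans.shape != (N_STATES, N_STATES):
            raise ValueError("pair-HMM must have exactly 5 states")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")
        if abs(self.match_emit.sum() - 1.0) > 1e-9:
            raise ValueError("match emission must be a distribution")
        if abs(self.ins_emit.sum() - 1.0) > 1e-9:
            raise ValueError("insert emission must be a distribution")
        if not np.allclose(self.match_emit, self.match_emit.T, atol=1e-12):
            raise ValueError("match emission must be exchange-symmetric")


@dataclass(frozen=True)
class PartitionParams:
    """Affine-gap Boltzmann ensemble: score table, gap penalties, beta."""

    scores: np.ndarray        # (K+1, K+1) symmetric substitution scores
    gap_open: float           # score of opening a gap (negative)
    gap_extend: float         # score of extending a gap (negative)
    beta: float               # inverse temperature, > 0
    alphabet: str = AMINO

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not np.allclose(self.scores, self.scores.T, atol=1e-12):
            raise ValueError("score table must be symmetric")


def default_hmm_params(alphabet: str = AMINO, overrides: dict | None = None) -> HmmParams:
    ov = dict(_HMM_DEFAULTS)
    pi = np.array(_HMM_PI)
    if overrides:
        for key in _HMM_DEFAULTS:
            if key in overrides:
                ov[key] = float(overrides[key])
        if "hmm_pi" in overrides:
            pi = np.asarray(overrides["hmm_pi"], dtype=float)
    pi = pi / pi.sum()
    d1, e1 = ov["hmm_gap_open_short"], ov["hmm_gap_extend_short"]
    d2, e2 = ov["hmm_gap_open_long"], ov["hmm_gap_extend_long"]
    trans = np.array([
        [1.0 - 2 * d1 - 2 * d2, d1, d1, d2, d2],
        [1.0 - e1, e1, 0.0, 0.0, 0.0],
        [1.0 - e1, 0.0, e1, 0.0, 0.0],
        [1.0 - e2, 0.0, 0.0, e2, 0.0],
        [1.0 - e2, 0.0, 0.0, 0.0, e2],
    ])
    if alphabet == AMINO:
        name = (overrides or {}).get("hmm_match_matrix", "BLOSUM62")
        joint = _joint_from_matrix(str(name), AMINO)
    else:
        joint = _nt_joint()
    ins = joint.sum(axis=1)
    return HmmParams(pi=pi, trans=trans, match_emit=joint, ins_emit=ins,
                     alphabet=alphabet)


def default_partition_params(alphabet: str = AMINO,
                             overrides: dict | None = None) -> PartitionParams:
    ov = overrides or {}
    order = alphabet_order(alphabet)
    k = len(order)
    scores = np.zeros((k + 1, k + 1))
    if alphabet == AMINO:
        name = str(ov.get("pf_matrix", "GONNET1992"))
        mat = substitution_matrices.load(name)
        for i, a in enumerate(order):
            for j, b in enumerate(order):
                scores[i, j] = mat[a, b]
        # GONNET1992 units are one tenth of the classic Gonnet table, hence
        # beta/gap values are the conventional T=5, -22/-1 point rescaled.
        go = float(ov.get("pf_gap_open", -2.2))
        ge = float(ov.get("pf_gap_extend", -0.1))
        beta = float(ov.get("pf_beta", 2.0))
    else:
        for i in range(k):
            for j in range(k):
                scores[i, j] = 5.0 if i == j else -4.0
        go = float(ov.get("pf_gap_open", -10.0))
        ge = float(ov.get("pf_gap_extend", -1.0))
        beta = float(ov.get("pf_beta", 0.4))
    # wildcard scores stay 0 (neutral)
    return PartitionParams(scores=scores, gap_open=go, gap_extend=ge,
                           beta=beta, alphabet=alphabet)


def parse_param_file(path) -> dict:
    """Parse a ``key = value`` parameter file; vectors are whitespace-split."""
    out: dict = {}
    with open(path, "rt", encoding="ascii") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            parts = value.split()
            if len(parts) > 1:
                out[key] = [float(p) for p in parts]
            else:
                try:
                    out[key] = float(value)
                except ValueError:
                    out[key] = value
    return out


def load_params(path=None, alphabet: str = AMINO) -> tuple[HmmParams, PartitionParams]:
    """Default HMM + partition parameters, optionally overridden from a file."""
    overrides = parse_param_file(path) if path is not None else None
    return (default_hmm_params(alphabet, overrides),
            default_partition_params(alphabet, overrides))
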