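"""Statistical coupling analysis (SCA) of multiple sequence alignments.

SCA measures conservation-weighted correlation between alignment positions:

    C~_ij^ab = phi_i^a phi_j^b (f_ij^ab - f_i^a f_j^b)

where f are (weighted, pseudocounted) single and joint amino-acid frequencies
and phi = d D / d f = ln[f(1-q)/(q(1-f))] is the gradient of the binary
Kullback-Leibler conservation measure D against the background frequency q.
The tensor is reduced to a positional matrix by the Frobenius norm over amino
acid pairs, and the top eigenmode of that matrix defines the sector — the
group of collectively coevolving positions; the rank-one reconstruction
C^ = lambda_1 v1 v1^T is the "cleaned" coevolution matrix used for comparison
with experimental couplings.  Ablations dropping either the conservation
weights or the correlations isolate each ingredient's contribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dca import ALPHABET, GAP

N_RES = 20
GAP_CODE = 20


def sequence_weights(msa: np.ndarray, identity_threshold: float = 0.8) -> np.ndarray:
    """Redundancy-correcting weights: 1 / (# sequences >= threshold identity).

    The count includes the sequence itself, so weights lie in (0, 1] and the
    sum is the effective number of sequences.
    """
    msa = np.asarray(msa)
    n, L = msa.shape
    # pairwise identity via one-hot inner products, blocked over rows
    q = int(msa.max()) + 1
    X = np.zeros((n, L * q), dtype=np.float32)
    X[np.repeat(np.arange(n), L), (msa + np.arange(L)[None, :] * q).ravel()] = 1.0
    ident = (X @ X.T) / L
    neighbors = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / neighbors


@dataclass
class AlignmentWithWeights:
    """Encoded alignment with sequence weights and pseudocounted frequencies.

    Gaps are treated as missing data by default: single-site frequencies are
    normalized over the 20 residues among non-gap entries, and joint
    frequencies over entries where both positions are residue-occupied.  With
    ``include_gaps`` the gap is a 21st state.  For gapless alignments the
    marginalization identity sum_b f_ij^ab = f_i^a holds exactly after
    pseudocounting.
    """

    msa: np.ndarray
    weights: np.ndarray | None = None
    pseudocount: float = 0.03
    include_gaps: bool = False
    identity_threshold: float = 0.8

    def __post_init__(self) -> None:
        self.msa = np.asarray(self.msa, dtype=np.int64)
        if self.msa.ndim != 2 or self.msa.size == 0:
            raise ValueError("alignment must be a non-empty (n, L) array")
        if self.weights is None:
            self.weights = sequence_weights(self.msa, self.identity_threshold)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("sequence weights must be positive")
        self._compute_frequencies()

    @property
    def n_seqs(self) -> int:
        return self.msa.shape[0]

    @property
    def n_positions(self) -> int:
        return self.msa.shape[1]

    @property
    def n_states(self) -> int:
        return N_RES + 1 if self.include_gaps else N_RES

    def _compute_frequencies(self) -> None:
        n, L = self.msa.shape
        q = self.n_states
        lam = self.pseudocount
        w = self.weights
        X = np.zeros((n, L, N_RES + 1), dtype=float)
        X[np.arange(n)[:, None], np.arange(L)[None, :], self.msa] = 1.0
        if self.include_gaps:
            Xq = X[:, :, :q]
        else:
            Xq = X[:, :, :N_RES]
        Xw = Xq * w[:, None, None]
        # single-site: normalize over observed (non-gap) weight per position
        obs = Xw.sum(axis=(0, 2))
        f1 = Xw.sum(axis=0) / obs[:, None]
        # joint: normalize per position pair over jointly observed weight
        Xf = Xq.reshape(n, L * q)
        Xwf = Xw.reshape(n, L * q)
        raw = Xwf.T @ Xf  # (L*q, L*q)
        raw = raw.reshape(L, q, L, q).transpose(0, 2, 1, 3)  # (L, L, q, q)
        pair_obs = raw.sum(axis=(2, 3))
        f2 = raw / pair_obs[:, :, None, None]
        self.f1 = (1 - lam) * f1 + lam / q
        self.f2 = (1 - lam) * f2 + lam / (q * q)
        # diagonal blocks: the joint of a position with itself is diag(f_i)
        idx = np.arange(L)
        diag_blocks = np.zeros((L, q, q))
        diag_blocks[:, np.arange(q), np.arange(q)] = self.f1
        self.f2[idx, idx] = diag_blocks


def conservation_phi(f: np.ndarray, q_background: float | np.ndarray = 0.05):
    """Conservation gradient phi and per-position KL conservation D.

    phi_i^a = ln[f(1-q)/(q(1-f))]; D_i^a = f ln(f/q) + (1-f) ln((1-f)/(1-q));
    the positional conservation D_i is the frequency-weighted sum of D_i^a.
    Frequencies must be pseudocounted into (0, 1).
    """
    f = np.asarray(f, dtype=float)
    q = np.broadcast_to(np.asarray(q_background, dtype=float), f.shape)
    if np.any(f <= 0) or np.any(f >= 1):
        raise ValueError("frequencies must lie strictly in (0, 1); apply a pseudocount")
    phi = np.log(f * (1 - q) / (q * (1 - f)))
    d_bin = f * np.log(f / q) + (1 - f) * np.log((1 - f) / (1 - q))
    d_pos = (f * np.log(f / q)).sum(axis=-1)
    return phi, d_bin, d_pos


@dataclass
class SCAResult:
    """Outputs of the SCA computation on one alignment."""

    phi: np.ndarray
    tensor: np.ndarray
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cleaned: np.ndarray
    sector: list
    d_positional: np.ndarray


def sca_matrix(aln: AlignmentWithWeights, q_background: float = 0.05, sector_quantile: float = 0.9) -> SCAResult:
    """Full SCA: tensor, positional matrix, eigenmodes, cleaned matrix, sector."""
    phi, _, d_pos = conservation_phi(aln.f1, q_background)
    corr = aln.f2 - aln.f1[:, None, :, None] * aln.f1[None, :, None, :]
    tensor = phi[:, None, :, None] * phi[None, :, None, :] * corr
    matrix = _frobenius(tensor)
    evals, evecs, cleaned, sector = top_mode_clean(matrix, sector_quantile)
    return SCAResult(
        phi=phi,
        tensor=tensor,
        matrix=matrix,
        eigenvalues=evals,
        eigenvectors=evecs,
        cleaned=cleaned,
        sector=sector,
        d_positional=d_pos,
    )


def _frobenius(tensor: np.ndarray) -> np.ndarray:
    m = np.sqrt((tensor**2).sum(axis=(2, 3)))
    np.fill_diagonal(m, 0.0)
    return m


def top_mode_clean(matrix: np.ndarray, sector_quantile: float = 0.9):
    """Eigendecompose; return (eigenvalues desc, eigenvectors, rank-1 cleaned
    matrix lambda_1 v1 v1^T, sector positions with |v1| above the quantile).

    v1's sign is fixed so its largest-magnitude entry is positive.  Positions
    are 1-based.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v1 = evecs[:, 0]
    if v1[np.argmax(np.abs(v1))] < 0:
        v1 = -v1
        evecs = evecs.copy()
        evecs[:, 0] = v1
    cleaned = evals[0] * np.outer(v1, v1)
    cut = np.quantile(np.abs(v1), sector_quantile)
    sector = [int(i) + 1 for i in np.where(np.abs(v1) >= cut)[0]]
    return evals, evecs, cleaned, sector


def ablation_matrices(aln: AlignmentWithWeights, q_background: float = 0.05):
    """The two SCA ablations: drop conservation weights, or drop correlations.

    no_weights: Frobenius norm of the raw correlation tensor f_ij - f_i f_j.
    no_correlation: outer product D_i D_j of positional conservation only
    (one documented interpretation of a correlation-free coevolution measure).
    """
    phi, _, d_pos = conservation_phi(aln.f1, q_background)
    corr = aln.f2 - aln.f1[:, None, :, None] * aln.f1[None, :, None, :]
    no_weights = _frobenius(corr)
    no_correlation = np.outer(d_pos, d_pos)
    np.fill_diagonal(no_correlation, 0.0)
    return no_weights, no_correlation
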