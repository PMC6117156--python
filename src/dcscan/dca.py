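"""Direct coupling analysis: Potts model inference by pseudolikelihood.

A Potts model assigns each aligned sequence sigma a statistical energy

    E(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)

with P(sigma) proportional to exp(-E(sigma)).  Fields h and couplings J are
inferred from a weighted alignment by L2-regularized pseudolikelihood
maximization (each column's conditional distribution given the rest), the
standard tractable alternative to full maximum likelihood.  Couplings are
symmetrized and reported in the zero-sum gauge, where Frobenius norms of the
J blocks (APC-corrected) are the usual contact scores.

The same model yields in-silico mutant cycles: the energetic effect of single
and double mutations away from a reference (wild-type) sequence, combined by
the thermodynamic cycle formula, gives a coupling ddE for every mutation pair
at every position pair — directly comparable to experimental ddG couplings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

#: canonical residue order; gap is the final state
AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AA20 + GAP


@dataclass
class PottsModel:
    """Fields and couplings over an L-position, q-state alphabet.

    ``J[i, j, a, b]`` is the coupling felt when position i carries state a and
    position j carries state b; symmetry ``J[i,j,a,b] == J[j,i,b,a]`` and zero
    diagonal blocks are maintained by all constructors here.
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: str = ALPHABET
    gauge: str = "none"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} incompatible with h shape {self.h.shape}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("non-finite model parameters")

    @property
    def n_positions(self) -> int:
        return self.h.shape[0]

    @property
    def n_states(self) -> int:
        return self.h.shape[1]

    @classmethod
    def zeros(cls, L: int, q: int = len(ALPHABET), alphabet: str | None = None) -> "PottsModel":
        alphabet = alphabet if alphabet is not None else ALPHABET[:q]
        return cls(np.zeros((L, q)), np.zeros((L, L, q, q)), alphabet=alphabet)

    def save(self, path) -> None:
        np.savez(path, h=self.h, J=self.J, alphabet=np.array(self.alphabet), gauge=np.array(self.gauge))

    @classmethod
    def load(cls, path) -> "PottsModel":
        d = np.load(path, allow_pickle=False)
        return cls(d["h"], d["J"], alphabet=str(d["alphabet"]), gauge=str(d["gauge"]))


def encode(sequences, alphabet: str = ALPHABET) -> np.ndarray:
    """Encode sequences (strings or iterables of letters) as integer codes."""
    lut = {c: k for k, c in enumerate(alphabet)}
    try:
        return np.array([[lut[c] for c in s] for s in sequences], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - message only
        raise ValueError(f"letter {e} not in model alphabet {alphabet!r}") from None


def decode(codes: np.ndarray, alphabet: str = ALPHABET) -> list[str]:
    arr = np.array(list(alphabet))
    return ["".join(arr[row]) for row in np.atleast_2d(codes)]


def statistical_energy(model: PottsModel, sequence) -> float:
    """E(sigma) = sum_i h_i(sigma_i) + sum_{i<j} J_ij(sigma_i, sigma_j)."""
    seq = _as_codes(model, sequence)
    L = model.n_positions
    if seq.shape[-1] != L:
        raise ValueError("sequence length does not match model")
    idx = np.arange(L)
    e = model.h[idx, seq].sum()
    iu, ju = np.triu_indices(L, k=1)
    e += model.J[iu, ju, seq[iu], seq[ju]].sum()
    return float(e)


def _as_codes(model: PottsModel, sequence) -> np.ndarray:
    if isinstance(sequence, str):
        return encode([sequence], model.alphabet)[0]
    seq = np.asarray(sequence)
    if seq.dtype.kind in "US":
        return encode(["".join(seq)], model.alphabet)[0]
    if seq.max(initial=0) >= model.n_states:
        raise ValueError("sequence codes exceed model alphabet")
    return seq.astype(np.int64)


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Re-express the model in the zero-sum (Ising) gauge.

    Each J block is doubly centred; the removed row/column means are absorbed
    into the fields, and the scalar means into per-position field offsets, so
    energy *differences* between any two sequences are unchanged.
    """
    J = model.J
    mean_b = J.mean(axis=3, keepdims=True)       # over second residue
    mean_a = J.mean(axis=2, keepdims=True)       # over first residue
    mean_ab = J.mean(axis=(2, 3), keepdims=True)
    Jz = J - mean_a - mean_b + mean_ab
    L = model.n_positions
    off = ~np.eye(L, dtype=bool)
    Jz[np.arange(L), np.arange(L)] = 0.0
    # fields absorb the per-(i,a) part of the removed means
    h = model.h + ((mean_b - mean_ab)[:, :, :, 0] * off[:, :, None]).sum(axis=1)
    h = h - h.mean(axis=1, keepdims=True)
    return PottsModel(h, Jz, alphabet=model.alphabet, gauge="zero-sum")


# ---------------------------------------------------------------------------
# pseudolikelihood fitting


def _plm_objective(theta, Xoh, w, L, q, lam_h, lam_j, diag_mask):
    """Negative weighted pseudo-log-likelihood + L2 penalty, with gradient.

    Parameters are h (L*q) and the asymmetric coupling matrix A (L*q, L*q)
    whose row block (i, :) holds site i's view of its couplings.  Conditional
    logits for site i, state a are -h_i(a) - sum_j A[ia, j sigma_j].
    """
    n = Xoh.shape[0]
    h = theta[: L * q]
    A = theta[L * q:].reshape(L * q, L * q)
    A = A * diag_mask
    logits = -(h[None, :] + Xoh @ A.T)  # (n, L*q)
    logits3 = logits.reshape(n, L, q)
    m = logits3.max(axis=2, keepdims=True)
    lse = m[:, :, 0] + np.log(np.exp(logits3 - m).sum(axis=2))
    ll_terms = (logits * Xoh).reshape(n, L, q).sum(axis=2) - lse  # (n, L)
    nll = -(w[:, None] * ll_terms).sum()

    P = np.exp(logits3 - lse[:, :, None]).reshape(n, L * q)
    G = w[:, None] * (P - Xoh)  # d nll / d logits
    grad_h = -G.sum(axis=0)
    grad_A = -(G.T @ Xoh) * diag_mask

    nll += lam_h * (h @ h) + lam_j * np.sum(A * A)
    grad_h += 2.0 * lam_h * h
    grad_A += 2.0 * lam_j * A
    return nll, np.concatenate([grad_h, grad_A.ravel()])


def fit_plm(
    msa: np.ndarray,
    weights: np.ndarray | None = None,
    lam_h: float = 0.01,
    lam_j: float | None = None,
    n_states: int | None = None,
    alphabet: str = ALPHABET,
    maxiter: int = 300,
    tol: float = 1e-6,
) -> tuple[PottsModel, dict]:
    """Infer a Potts model from an encoded alignment by pseudolikelihood.

    msa : (n, L) integer codes; weights : per-sequence weights (default 1).
    lam_j defaults to 0.01*(L-1), the plmDCA-style scaling.  Returns the
    symmetrized, zero-sum-gauge model and an info dict (converged flag, final
    gradient norm, iterations, penalized objective).
    """
    msa = np.asarray(msa, dtype=np.int64)
    n, L = msa.shape
    if L < 2:
        raise ValueError("alignment must have at least two positions")
    q = int(n_states) if n_states is not None else int(msa.max()) + 1
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if lam_j is None:
        lam_j = 0.01 * (L - 1)

    Xoh = np.zeros((n, L * q))
    Xoh[np.repeat(np.arange(n), L), (msa + np.arange(L)[None, :] * q).ravel()] = 1.0
    diag_mask = np.kron(1.0 - np.eye(L), np.ones((q, q)))

    theta0 = np.zeros(L * q + (L * q) ** 2)
    res = minimize(
        _plm_objective,
        theta0,
        args=(Xoh, w, L, q, lam_h, lam_j, diag_mask),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 2 * maxiter, "ftol": 1e-15, "gtol": tol},
    )
    h = res.x[: L * q].reshape(L, q)
    A = (res.x[L * q:].reshape(L * q, L * q) * diag_mask).reshape(L, q, L, q)
    J = 0.5 * (A.transpose(0, 2, 1, 3) + A.transpose(2, 0, 3, 1))  # (L, L, q, q)
    model = zero_sum_gauge(PottsModel(h, J, alphabet=alphabet[:q], gauge="none"))
    info = {
        "converged": bool(res.success),
        "grad_norm": float(np.abs(res.jac).max()),
        "n_iter": int(res.nit),
        "objective": float(res.fun),
        "message": str(res.message),
    }
    return model, info


# ---------------------------------------------------------------------------
# mutational couplings and contact scores


def _wt_onehot(model: PottsModel, wt: np.ndarray) -> np.ndarray:
    W = np.zeros((model.n_positions, model.n_states))
    W[np.arange(model.n_positions), wt] = 1.0
    return W


def single_mutant_energies(model: PottsModel, wt_codes: np.ndarray) -> np.ndarray:
    """dE[i, a] = E(wt with position i -> a) - E(wt), for residue states only."""
    wt = _as_codes(model, wt_codes)
    L = model.n_positions
    n_res = min(20, model.n_states)
    idx = np.arange(L)
    W = _wt_onehot(model, wt)
    coupl = np.einsum("ijab,jb->ia", model.J, W)  # sum_j J_ij(a, wt_j)
    tot = model.h + coupl
    return tot[:, :n_res] - tot[idx, wt][:, None]


def pair_coupling_tensor(model: PottsModel, wt_codes: np.ndarray) -> np.ndarray:
    """Mutant-cycle couplings ddE[i, j, x, y] from the model, residue states only.

    ddE = (dE_i^x + dE_j^y) - dE_ij^xy, which for a pairwise model reduces to
    -(J_ij(x,y) - J_ij(x, wt_j) - J_ij(wt_i, y) + J_ij(wt_i, wt_j)).
    """
    wt = _as_codes(model, wt_codes)
    L = model.n_positions
    n_res = min(20, model.n_states)
    idx = np.arange(L)
    J = model.J
    W = _wt_onehot(model, wt)
    term_xy = J[:, :, :n_res, :n_res]
    term_xw = np.einsum("ijab,jb->ija", J, W)[:, :, :n_res]  # J_ij(x, wt_j)
    term_wy = np.einsum("ijab,ia->ijb", J, W)[:, :, :n_res]  # J_ij(wt_i, y)
    term_ww = np.einsum("ijab,ia,jb->ij", J, W, W)
    dde = -(term_xy - term_xw[:, :, :, None] - term_wy[:, :, None, :] + term_ww[:, :, None, None])
    dde[idx, idx] = 0.0
    return dde


def dca_mutant_cycles(model: PottsModel, wt_sequences: dict) -> "pd.DataFrame":
    """Per-homolog mutant-cycle couplings ddE from the model (long format).

    wt_sequences maps homolog name -> wild-type sequence in the model frame.
    Mutations to the wild-type residue itself are excluded; gap is never a
    mutation.  Output columns match the experimental coupling tables so the
    same homolog-averaging and mixture-model machinery applies downstream.
    """
    import pandas as pd

    frames = []
    n_res = min(20, model.n_states)
    L = model.n_positions
    iu, ju = np.triu_indices(L, k=1)
    for hom, seq in wt_sequences.items():
        wt = _as_codes(model, seq)
        dde = pair_coupling_tensor(model, wt)
        for i, j in zip(iu, ju):
            xs, ys = np.meshgrid(np.arange(n_res), np.arange(n_res), indexing="ij")
            keep = (xs != wt[i]) & (ys != wt[j])
            frames.append(
                pd.DataFrame(
                    {
                        "homolog": hom,
                        "pos_i": i + 1,
                        "pos_j": j + 1,
                        "aa_x": np.array(list(model.alphabet))[xs[keep]],
                        "aa_y": np.array(list(model.alphabet))[ys[keep]],
                        "ddg": dde[i, j][keep],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def apc_correct(F: np.ndarray) -> np.ndarray:
    """Average product correction: F_ij - (F_i. * F_.j) / F_.. .

    Row/column/total means are taken over the full matrix; an exactly rank-1
    input is annihilated (the correction removes the entire separable part).
    """
    F = np.asarray(F, dtype=float)
    row = F.mean(axis=1)
    tot = F.mean()
    if tot == 0:
        return F.copy()
    return F - np.outer(row, row) / tot


def coupling_scores(
    model: PottsModel,
    min_separation: int = 3,
    apc: bool = True,
    residues_only: bool = True,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Frobenius-norm coupling scores per position pair, APC-corrected.

    Returns (score matrix with excluded pairs as NaN, pairs ranked by
    decreasing score).  Pairs closer than ``min_separation`` in sequence are
    excluded from the ranking, the usual convention for contact prediction.
    APC subtracts S_i. S_.j / S.. from each entry to remove background
    row/column effects.
    """
    m = model if model.gauge == "zero-sum" else zero_sum_gauge(model)
    J = m.J[:, :, :20, :20] if residues_only and m.n_states > 20 else m.J
    F = np.sqrt((J**2).sum(axis=(2, 3)))
    L = F.shape[0]
    np.fill_diagonal(F, 0.0)
    S = apc_correct(F) if apc else F.copy()
    np.fill_diagonal(S, np.nan)
    ii, jj = np.triu_indices(L, k=1)
    mask = (jj - ii) >= min_separation
    scores = np.full((L, L), np.nan)
    scores[ii[mask], jj[mask]] = S[ii[mask], jj[mask]]
    scores[jj[mask], ii[mask]] = S[ii[mask], jj[mask]]
    order = np.argsort(-S[ii[mask], jj[mask]], kind="stable")
    ranked = [(int(ii[mask][k]) + 1, int(jj[mask][k]) + 1) for k in order]
    return scores, ranked


def top_set(ranked_pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Top-k pairs of a ranking (e.g. k = L//2 for contact prediction)."""
    return list(ranked_pairs)[:k]


def scramble_noncontact(
    model: PottsModel,
    contacts,
    n_top: int | None = None,
    min_separation: int = 3,
    seed: int | np.random.Generator = 0,
) -> tuple[PottsModel, list[tuple[int, int]]]:
    """Edited model: keep top contact couplings, permute all other J blocks.

    The retained set defaults to the top L//2 APC-ranked pairs that are in the
    contact map.  Every other position pair's J block is moved wholesale to a
    different (random) non-retained pair, preserving the multiset of blocks;
    within-block structure is untouched.  Returns (edited model, retained
    pairs, 1-based).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = model.n_positions
    if n_top is None:
        n_top = L // 2
    contact_set = {(min(i, j), max(i, j)) for i, j in contacts}
    _, ranked = coupling_scores(model, min_separation=min_separation)
    retained = [p for p in top_set(ranked, n_top) if p in contact_set]
    retained_set = set(retained)

    iu, ju = np.triu_indices(L, k=1)
    others = [(int(i) + 1, int(j) + 1) for i, j in zip(iu, ju) if (int(i) + 1, int(j) + 1) not in retained_set]
    perm = rng.permutation(len(others))
    J = model.J.copy()
    src_blocks = [model.J[i - 1, j - 1].copy() for i, j in others]
    for (i, j), k in zip(others, perm):
        block = src_blocks[k]
        J[i - 1, j - 1] = block
        J[j - 1, i - 1] = block.T
    edited = PottsModel(model.h.copy(), J, alphabet=model.alphabet, gauge=model.gauge)
    return edited, retained
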