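"""Adaptive Sum of Powered score (aSPU) multi-trait test on GWAS Z-scores.

For one SNP with Z-scores S_p across K analysis traits, the powered-score
statistic is SPU(gamma) = sum_p S_p^gamma. Small gamma pools dense,
same-signed signal; large gamma concentrates on the strongest trait. The adaptive test
takes the minimum Monte-Carlo p-value over a gamma grid and assigns that
minimum its own Monte-Carlo p-value by ranking each null draw's minimum
against all draws. Null draws are multivariate normal with the between-trait
correlation of null Z-scores, estimated genome-wide from SNPs with no
evidence of association.

Two interchangeable evaluation paths are implemented: a vectorized
in-memory path for moderate Monte-Carlo sizes and a two-pass streaming path
for large ones; both consume the identical chunked draw stream and agree
exactly, draw for draw. A staged schedule escalates only promising SNPs to
larger Monte-Carlo sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GAMMAS = (1, 2, 3, 4, 5, 6, 7, 8)
DEFAULT_SCHEDULE = (10_000, 1_000_000, 100_000_000)

_CHUNK = 1 << 19  # draws per chunk in the shared stream
_IN_MEMORY_MAX = 2_000_000


@dataclass
class NullCorr:
    """K x K correlation of null Z-scores across analysis traits."""

    R: np.ndarray
    traits: list[str]
    n_snps_used: int
    selection_rule: str

    def submatrix(self, mask: np.ndarray) -> np.ndarray:
        idx = np.where(mask)[0]
        return self.R[np.ix_(idx, idx)]


@dataclass
class AspuResult:
    snp_id: str
    p_gamma: dict[int, float]
    gamma_min: int
    p_aspu: float
    b_used: int
    seed: int
    traits_used: list[str] = field(default_factory=list)


def spu_statistic(z: np.ndarray, gamma: float,
                  available: np.ndarray | None = None) -> float:
    """SPU(gamma) over available traits; downstream comparisons use |SPU|.

    ``gamma=inf`` gives the max-|Z| variant.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    z = np.asarray(z, dtype=float)
    if available is not None:
        z = z[np.asarray(available, dtype=bool)]
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no available traits for this SNP")
    if np.isinf(gamma):
        return float(np.max(np.abs(z)))
    return float(np.sum(z**gamma))


def estimate_null_corr(
    z_df: pd.DataFrame,
    traits: list[str],
    *,
    z_max: float = 2.0,
    thin: int = 100,
    min_snps: int = 1000,
    sort_by: tuple[str, str] = ("CHR", "POS"),
) -> NullCorr:
    """Estimate the null Z correlation from genome-wide summary Z-scores.

    Keeps SNPs with |z| < ``z_max`` on every available trait, thins to
    every ``thin``-th SNP in position order (an LD-pruning stand-in), and
    takes the pairwise-complete Pearson correlation. Non-positive-definite
    estimates are ridge-repaired toward the identity.
    """
    df = z_df
    if all(c in df.columns for c in sort_by):
        df = df.sort_values(list(sort_by), kind="mergesort")
    Z = df[traits].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ok = np.all((np.abs(Z) < z_max) | np.isnan(Z), axis=1)
    ok &= ~np.all(np.isnan(Z), axis=1)
    sel = df.loc[ok, traits].iloc[::thin]
    if len(sel) < min_snps:
        raise ValueError(
            f"only {len(sel)} null SNPs after selection (need {min_snps}); "
            "relax thinning or the |z| cutoff"
        )
    R = sel.corr(min_periods=2).to_numpy()
    R = np.where(np.isnan(R), 0.0, R)
    np.fill_diagonal(R, 1.0)
    R = _ridge_repair(R)
    return NullCorr(
        R=R,
        traits=list(traits),
        n_snps_used=len(sel),
        selection_rule=f"all-trait |z|<{z_max}, 1-in-{thin} thinning",
    )


def _ridge_repair(R: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    lam = 0.0
    while np.linalg.eigvalsh(R).min() < min_eig:
        lam = max(2.0 * lam, 1e-4)
        R = (1.0 - lam) * R + lam * np.eye(R.shape[0])
        np.fill_diagonal(R, 1.0)
        if lam >= 1.0:
            break
    return R


# --- shared reproducible draw stream -----------------------------------

def _draw_stream(seed_seq: np.random.SeedSequence, B: int, chol: np.ndarray):
    """Yield chunks of null SPU draws; identical across re-iterations."""
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    k = chol.shape[0]
    done = 0
    while done < B:
        m = min(_CHUNK, B - done)
        yield rng.standard_normal((m, k)) @ chol.T
        done += m


def _abs_spu(Z0: np.ndarray, gammas: tuple[float, ...]) -> np.ndarray:
    """|SPU(gamma)| for every draw: rows = draws, cols = sorted gammas.

    Powers are built cumulatively; gamma = inf (sorted last) is max-|Z|.
    """
    out = np.empty((Z0.shape[0], len(gammas)))
    power = np.ones_like(Z0)
    g_prev = 0
    for j, g in enumerate(sorted(gammas)):
        if np.isinf(g):
            out[:, j] = np.abs(Z0).max(axis=1)
            continue
        power = power * Z0 ** (int(g) - g_prev)
        g_prev = int(g)
        out[:, j] = np.abs(power.sum(axis=1))
    return out


def _obs_abs_spu(z: np.ndarray, gammas: tuple[int, ...]) -> np.ndarray:
    return np.array([abs(spu_statistic(z, g)) for g in sorted(gammas)])


def _aspu_in_memory(
    z_obs: np.ndarray, chol: np.ndarray, gammas: tuple[int, ...],
    B: int, seed_seq: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact MC evaluation holding all draws' statistics in memory.

    z_obs is (n_snps, k). Returns (p_gamma matrix, p_aspu vector).
    """
    gammas = tuple(sorted(gammas))
    S = np.concatenate(
        [_abs_spu(chunk, gammas) for chunk in _draw_stream(seed_seq, B, chol)]
    )
    obs = np.vstack([_obs_abs_spu(z, gammas) for z in z_obs])
    G = len(gammas)
    counts_obs = np.empty((z_obs.shape[0], G), dtype=np.int64)
    cmin = np.full(B, np.iinfo(np.int64).max, dtype=np.int64)
    for j in range(G):
        col_sorted = np.sort(S[:, j])
        counts_obs[:, j] = B - np.searchsorted(col_sorted, obs[:, j],
                                               side="left")
        counts_draw = B - np.searchsorted(col_sorted, S[:, j], side="left")
        np.minimum(cmin, counts_draw, out=cmin)
    p_gamma = (1.0 + counts_obs) / (B + 1.0)
    cmin_obs = counts_obs.min(axis=1)
    # integer threshold C = floor(B * min_gamma p_gamma) without float error
    C = (B * (1 + cmin_obs)) // (B + 1)
    cmin_sorted = np.sort(cmin)
    num = np.searchsorted(cmin_sorted, C, side="right")
    p_aspu = (1.0 + num) / (B + 1.0)
    return p_gamma, p_aspu


def _aspu_streaming(
    z_obs: np.ndarray, chol: np.ndarray, gammas: tuple[int, ...],
    B: int, seed_seq: np.random.SeedSequence, topk: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass streaming evaluation, exact and identical to the in-memory
    path on the same draw stream.

    Pass 1 accumulates exceedance counts against the observed statistics and
    the ``topk`` largest null |SPU| values per gamma. A draw contributes to
    the adaptive numerator iff for some gamma its |SPU| strictly exceeds the
    (C+1)-th largest null value, where C = floor(B * min_gamma p_gamma);
    pass 2 counts those draws.
    """
    gammas = tuple(sorted(gammas))
    G = len(gammas)
    n_obs = z_obs.shape[0]
    obs = np.vstack([_obs_abs_spu(z, gammas) for z in z_obs])
    counts_obs = np.zeros((n_obs, G), dtype=np.int64)
    tops: list[np.ndarray] = [np.empty(0) for _ in range(G)]
    for chunk in _draw_stream(seed_seq, B, chol):
        S = _abs_spu(chunk, gammas)
        for j in range(G):
            counts_obs[:, j] += (S[:, j][None, :] >= obs[:, j][:, None]).sum(
                axis=1
            )
            merged = np.concatenate([tops[j], S[:, j]])
            if merged.size > topk:
                merged = np.partition(merged, merged.size - topk)[-topk:]
            tops[j] = merged
    for j in range(G):
        tops[j] = np.sort(tops[j])[::-1]  # descending

    p_gamma = (1.0 + counts_obs) / (B + 1.0)
    cmin_obs = counts_obs.min(axis=1)
    C = (B * (1 + cmin_obs)) // (B + 1)
    if np.any(C >= topk):
        raise RuntimeError(
            "streaming top-k buffer too small for the observed p-value; "
            "increase topk or use the in-memory path"
        )
    # per-SNP, per-gamma strict thresholds: the (C+1)-th largest value
    thresh = np.empty((n_obs, G))
    for j in range(G):
        thresh[:, j] = tops[j][C]
    num = np.zeros(n_obs, dtype=np.int64)
    for chunk in _draw_stream(seed_seq, B, chol):
        S = _abs_spu(chunk, gammas)
        for i in range(n_obs):
            hit = np.zeros(S.shape[0], dtype=bool)
            for j in range(G):
                hit |= S[:, j] > thresh[i, j]
            num[i] += int(hit.sum())
    p_aspu = (1.0 + num) / (B + 1.0)
    return p_gamma, p_aspu


def _mask_seed_seq(seed: int, stage: int, mask: np.ndarray
                   ) -> np.random.SeedSequence:
    """Deterministic stream key per (stage, availability mask); SNPs that
    share a mask share null draws, so results do not depend on SNP order."""
    bits = int("".join("1" if m else "0" for m in mask), 2)
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(stage, bits))


def _chol_or_raise(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("null correlation submatrix is not "
                         "positive-definite") from exc


def aspu_single(
    z: np.ndarray,
    R: np.ndarray | NullCorr,
    gammas: tuple[int, ...] = DEFAULT_GAMMAS,
    B: int = 10_000,
    seed: int = 0,
    snp_id: str = "snp",
) -> AspuResult:
    """aSPU test for one SNP at a fixed Monte-Carlo size B.

    Unavailable traits (NaN in ``z``) are dropped together with the matching
    rows/columns of R. P-values use the add-one estimator (1+x)/(B+1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if not gammas:
        raise ValueError("gammas must be nonempty")
    z = np.asarray(z, dtype=float)
    mask = np.isfinite(z)
    if not mask.any():
        raise ValueError("no available traits")
    Rm = R.submatrix(mask) if isinstance(R, NullCorr) else \
        np.asarray(R)[np.ix_(np.where(mask)[0], np.where(mask)[0])]
    chol = _chol_or_raise(Rm)
    seed_seq = _mask_seed_seq(seed, 0, mask)
    zs = z[mask][None, :]
    if B <= _IN_MEMORY_MAX:
        p_gamma, p_aspu = _aspu_in_memory(zs, chol, gammas, B, seed_seq)
    else:
        p_gamma, p_aspu = _aspu_streaming(
            zs, chol, gammas, B, seed_seq, topk=_default_topk(B, B)
        )
    gs = tuple(sorted(gammas))
    pg = dict(zip(gs, p_gamma[0]))
    gamma_min = min(pg, key=lambda g: (pg[g], g))
    traits = [f"trait{i}" for i in np.where(mask)[0]]
    return AspuResult(snp_id, pg, gamma_min, float(p_aspu[0]), B, seed,
                      traits)


def _default_topk(B: int, B_prev: int, c: float = 100.0) -> int:
    return int(min(B, np.ceil(8.0 * B * c / B_prev) + 4096))


def aspu_scan(
    z_df: pd.DataFrame,
    R: NullCorr,
    *,
    gammas: tuple[int, ...] = DEFAULT_GAMMAS,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    escalation_c: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Staged aSPU scan over many SNPs.

    ``z_df`` has one row per SNP with a ``SNP`` column and one Z column per
    trait in ``R.traits`` (NaN marks an unavailable trait). Every SNP is
    evaluated at the first Monte-Carlo size; SNPs with
    p_aspu <= escalation_c / B move to the next stage. Null draws are
    shared within a stage across SNPs with the same availability mask.
    """
    if list(schedule) != sorted(schedule):
        raise ValueError("schedule must be increasing")
    traits = R.traits
    Z = z_df[traits].to_numpy(dtype=float)
    snps = z_df["SNP"].to_numpy()
    masks = np.isfinite(Z)
    if not masks.any(axis=1).all():
        raise ValueError("every SNP needs at least one available trait")

    gs = tuple(sorted(gammas))
    n = len(snps)
    p_gamma = np.full((n, len(gs)), np.nan)
    p_aspu = np.full(n, np.nan)
    b_used = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)

    for stage, B in enumerate(schedule):
        if not active.any():
            break
        B_prev = schedule[stage - 1] if stage else None
        idx_active = np.where(active)[0]
        # group by availability mask
        keys = {}
        for i in idx_active:
            keys.setdefault(masks[i].tobytes(), []).append(i)
        for key, members in keys.items():
            mask = np.frombuffer(key, dtype=bool)
            cols = np.where(mask)[0]
            chol = _chol_or_raise(R.R[np.ix_(cols, cols)])
            seed_seq = _mask_seed_seq(seed, stage, mask)
            zs = Z[np.ix_(members, cols)]
            if B <= _IN_MEMORY_MAX:
                pg, pa = _aspu_in_memory(zs, chol, gs, B, seed_seq)
            else:
                topk = _default_topk(B, B_prev or B, escalation_c)
                pg, pa = _aspu_streaming(zs, chol, gs, B, seed_seq, topk)
            p_gamma[members] = pg
            p_aspu[members] = pa
            b_used[members] = B
        threshold = escalation_c / B
        active &= p_aspu <= threshold

    out = pd.DataFrame({"SNP": snps})
    for j, g in enumerate(gs):
        out[f"P_SPU{g}"] = p_gamma[:, j]
    out["GAMMA_MIN"] = [gs[j] for j in np.argmin(p_gamma, axis=1)]
    out["P_ASPU"] = p_aspu
    out["B_USED"] = b_used
    out["TRAITS_USED"] = [
        ",".join(t for t, m in zip(traits, row) if m) for row in masks
    ]
    return out


def aspu_naive_oracle(
    z: np.ndarray,
    R: np.ndarray,
    gammas: tuple[int, ...],
    B: int,
    seed: int = 0,
) -> tuple[dict[int, float], float]:
    """Reference O(B^2) implementation for validation on small B.

    Re-ranks every draw against all draws by direct comparison; shares the
    draw stream (and therefore must agree exactly) with the fast paths.
    """
    z = np.asarray(z, dtype=float)
    mask = np.isfinite(z)
    cols = np.where(mask)[0]
    chol = _chol_or_raise(np.asarray(R)[np.ix_(cols, cols)])
    seed_seq = _mask_seed_seq(seed, 0, mask)
    Z0 = np.concatenate(list(_draw_stream(seed_seq, B, chol)))
    gs = tuple(sorted(gammas))
    S = _abs_spu(Z0, gs)
    obs = _obs_abs_spu(z[mask], gs)
    p_gamma = {}
    counts_draw = np.empty((B, len(gs)), dtype=np.int64)
    for j, g in enumerate(gs):
        p_gamma[g] = (1.0 + np.sum(S[:, j] >= obs[j])) / (B + 1.0)
        for b in range(B):
            counts_draw[b, j] = np.sum(S[:, j] >= S[b, j])
    cmin = counts_draw.min(axis=1)
    cmin_obs = min(int(np.sum(S[:, j] >= obs[j])) for j in range(len(gs)))
    C = (B * (1 + cmin_obs)) // (B + 1)
    p_aspu = (1.0 + int(np.sum(cmin <= C))) / (B + 1.0)
    return p_gamma, p_aspu
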