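"""Scaling, indexing-ambiguity resolution, symmetry merging and export.

Merging statistics follow the serial-crystallography conventions:

    R_merge = Σ_u Σ_i |I_i − ⟨I⟩_u| / Σ_u Σ_i I_i
    R_meas  = Σ_u √(n_u/(n_u−1)) Σ_i |I_i − ⟨I⟩_u| / Σ_u Σ_i I_i
    R_pim   = Σ_u √(1/(n_u−1)) Σ_i |I_i − ⟨I⟩_u| / Σ_u Σ_i I_i
    R_split = (1/√2) Σ_u |I_A − I_B| / (½ Σ_u (I_A + I_B))
    CC_1/2  = Pearson correlation of the half-dataset means

with sums over uniques of multiplicity ≥ 2 for the R statistics, ⟨I⟩ the
1/σ²-weighted mean, and the A/B halves assigned alternately in frame-id
order (deterministic, no RNG).  These are descriptive outputs: still data
with partiality corrections can show R_merge well above 100% yet still
solve structures, so nothing gates on them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import symmetry
from .exceptions import InsufficientDataError, InvalidArgumentError
from .geometry import UnitCell

logger = logging.getLogger(__name__)

__all__ = [
    "MergeStats",
    "resolve_indexing_ambiguity",
    "scale_frames",
    "merge",
    "completeness",
    "write_hkl",
    "read_hkl",
]


@dataclass
class MergeStats:
    r_merge: float
    r_meas: float
    r_pim: float
    r_split: float
    cc_half: float
    completeness: float
    mean_multiplicity: float
    n_unique: int
    n_observations: int
    d_min: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _unique_frame(obs: pd.DataFrame, laue_group: str) -> pd.DataFrame:
    out = obs.copy()
    reps = symmetry.unique_hkl(out[["h", "k", "l"]].to_numpy(int), laue_group)
    out[["hu", "ku", "lu"]] = reps
    return out


def resolve_indexing_ambiguity(
    datasets: list[pd.DataFrame],
    twin_ops: list[np.ndarray],
    laue_group: str,
    intensity_col: str = "I",
    n_passes: int = 2,
) -> tuple[list[pd.DataFrame], list[int], list[bool]]:
    """Bring merohedrally ambiguous datasets onto one indexing convention.

    Each dataset is reindexed by the operator maximizing the Pearson
    correlation of its per-unique mean intensities with a running reference;
    the first dataset seeds the reference and two passes are run so early
    choices can be revisited.  Deterministic given the dataset order.

    Returns (reindexed datasets, chosen operator index per dataset, flags
    marking datasets left on identity for lack of common reflections).
    """
    if not twin_ops:
        twin_ops = [np.eye(3, dtype=int)]
    if not np.array_equal(twin_ops[0], np.eye(3, dtype=int)):
        twin_ops = [np.eye(3, dtype=int)] + list(twin_ops)
    if len(twin_ops) == 1:
        return list(datasets), [0] * len(datasets), [False] * len(datasets)

    choices = [0] * len(datasets)
    flagged = [False] * len(datasets)

    def dataset_means(df: pd.DataFrame, op: np.ndarray) -> pd.Series:
        hkl = df[["h", "k", "l"]].to_numpy(int) @ op.T
        reps = symmetry.unique_hkl(hkl, laue_group)
        tmp = pd.DataFrame({"key": list(map(tuple, reps)), "I": df[intensity_col].to_numpy()})
        return tmp.groupby("key")["I"].mean()

    for _ in range(n_passes):
        reference: dict[tuple, tuple[float, int]] = {}

        def ref_add(means: pd.Series) -> None:
            for key, val in means.items():
                tot, n = reference.get(key, (0.0, 0))
                reference[key] = (tot + val, n + 1)

        for di, df in enumerate(datasets):
            if not reference:
                ref_add(dataset_means(df, twin_ops[choices[di]]))
                continue
            best_op, best_corr = choices[di], -np.inf
            any_overlap = False
            for oi, op in enumerate(twin_ops):
                means = dataset_means(df, op)
                common = [k for k in means.index if k in reference]
                if len(common) < 3:
                    continue
                any_overlap = True
                ref_vals = np.array([reference[k][0] / reference[k][1] for k in common])
                own_vals = means.loc[common].to_numpy()
                if np.std(ref_vals) == 0 or np.std(own_vals) == 0:
                    continue
                corr = float(np.corrcoef(ref_vals, own_vals)[0, 1])
                if corr > best_corr:
                    best_corr, best_op = corr, oi
            if not any_overlap:
                flagged[di] = True
                best_op = 0
            choices[di] = best_op
            ref_add(dataset_means(df, twin_ops[best_op]))

    out = []
    for df, ci in zip(datasets, choices):
        new = df.copy()
        new[["h", "k", "l"]] = df[["h", "k", "l"]].to_numpy(int) @ twin_ops[ci].T
        out.append(new)
    return out, choices, flagged


def scale_frames(
    obs: pd.DataFrame,
    laue_group: str,
    intensity_col: str = "I_corr",
    sigma_col: str = "sigma_corr",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> pd.Series:
    """Multiplicative per-frame scale factors by alternating least squares.

    Minimizes Σ w (I_obs/k_f − ⟨I⟩_u)² with w = 1/σ², alternating between
    unique-reflection means and frame scales until the largest relative
    scale change drops below ``tol``.  The first frame of each connected
    component of the frame/reflection graph fixes the gauge (scale 1);
    disconnected components are scaled independently with a warning.
    """
    df = _unique_frame(obs, laue_group)
    frames = np.sort(df["frame_id"].unique())
    if len(frames) < 2:
        return pd.Series(np.ones(len(frames)), index=frames, name="scale")
    f_idx = pd.Categorical(df["frame_id"], categories=frames).codes
    uniq_keys, u_idx = np.unique(df[["hu", "ku", "lu"]].to_numpy(), axis=0, return_inverse=True)

    inc = coo_matrix((np.ones(len(df)), (f_idx, u_idx)), shape=(len(frames), len(uniq_keys)))
    n_comp, comp = connected_components(inc @ inc.T, directed=False)
    if n_comp > 1:
        warnings.warn(f"frame graph has {n_comp} disconnected components; scaled independently")

    intensity = df[intensity_col].to_numpy(float)
    weight = 1.0 / np.square(df[sigma_col].to_numpy(float))
    scales = np.ones(len(frames))
    for _ in range(max_iter):
        k_per_obs = scales[f_idx]
        num = np.bincount(u_idx, weights=weight * intensity / k_per_obs, minlength=len(uniq_keys))
        den = np.bincount(u_idx, weights=weight, minlength=len(uniq_keys))
        means = num / np.maximum(den, 1e-300)
        m_per_obs = means[u_idx]
        k_num = np.bincount(f_idx, weights=weight * intensity * m_per_obs, minlength=len(frames))
        k_den = np.bincount(f_idx, weights=weight * m_per_obs**2, minlength=len(frames))
        new_scales = np.where(k_den > 0, k_num / np.maximum(k_den, 1e-300), scales)
        # gauge: first frame of each component at scale 1
        for ci in range(n_comp):
            members = np.flatnonzero(comp == ci)
            new_scales[members] /= new_scales[members[0]]
        change = np.max(np.abs(new_scales - scales) / np.maximum(np.abs(scales), 1e-12))
        scales = new_scales
        if change < tol:
            break
    return pd.Series(scales, index=frames, name="scale")


def merge(
    obs: pd.DataFrame,
    laue_group: str,
    cell: UnitCell | None = None,
    d_min: float | None = None,
    intensity_col: str = "I_corr",
    sigma_col: str = "sigma_corr",
) -> tuple[pd.DataFrame, MergeStats]:
    """Merge scaled observations into Laue-unique reflections + statistics.

    Input must already be scaled and ambiguity-resolved.  Returns a table
    (h, k, l, I, sigma, multiplicity) of weighted means and the overall
    :class:`MergeStats`.  Uniques observed once contribute to completeness
    and the merged list but are excluded from the R statistics.
    """
    if len(obs) == 0:
        raise InsufficientDataError("no observations to merge")
    df = _unique_frame(obs, laue_group)
    df["w"] = 1.0 / np.square(df[sigma_col].to_numpy(float))
    df["wi"] = df["w"] * df[intensity_col]

    grouped = df.groupby(["hu", "ku", "lu"], sort=True)
    agg = grouped.agg(n=("w", "size"), sw=("w", "sum"), swi=("wi", "sum"))
    agg["I"] = agg["swi"] / agg["sw"]
    agg["sigma"] = np.sqrt(1.0 / agg["sw"])

    mean_per_obs = agg["I"].reindex(
        pd.MultiIndex.from_arrays([df["hu"], df["ku"], df["lu"]])
    ).to_numpy()
    n_per_obs = agg["n"].reindex(
        pd.MultiIndex.from_arrays([df["hu"], df["ku"], df["lu"]])
    ).to_numpy()
    dev = np.abs(df[intensity_col].to_numpy(float) - mean_per_obs)
    multi = n_per_obs >= 2

    denom = float(np.sum(df[intensity_col].to_numpy(float)[multi]))
    keys = list(zip(df["hu"], df["ku"], df["lu"]))
    dev_sums = pd.Series(dev, index=pd.MultiIndex.from_tuples(keys)).groupby(level=[0, 1, 2]).sum()
    n_u = agg["n"]
    multi_u = n_u >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_merge = float(dev_sums[multi_u].sum() / denom) if denom > 0 else float("nan")
        r_meas = (
            float((np.sqrt(n_u[multi_u] / (n_u[multi_u] - 1)) * dev_sums[multi_u]).sum() / denom)
            if denom > 0 else float("nan")
        )
        r_pim = (
            float((np.sqrt(1.0 / (n_u[multi_u] - 1)) * dev_sums[multi_u]).sum() / denom)
            if denom > 0 else float("nan")
        )

    # deterministic half-dataset split: alternate in frame-id order per unique
    df_sorted = df.sort_values(["hu", "ku", "lu", "frame_id"], kind="mergesort")
    parity = df_sorted.groupby(["hu", "ku", "lu"], sort=False).cumcount() % 2
    df_sorted["half"] = np.where(parity == 0, "A", "B")
    halves = df_sorted.groupby(["hu", "ku", "lu", "half"])[intensity_col].mean().unstack("half")
    both = halves.dropna(subset=["A", "B"]) if {"A", "B"} <= set(halves.columns) else halves.iloc[0:0]
    if len(both) >= 2:
        ia, ib = both["A"].to_numpy(), both["B"].to_numpy()
        cc_half = float(np.corrcoef(ia, ib)[0, 1]) if np.std(ia) > 0 and np.std(ib) > 0 else float("nan")
        tot = 0.5 * float(np.sum(ia + ib))
        r_split = float(np.sum(np.abs(ia - ib)) / (np.sqrt(2.0) * tot)) if tot != 0 else float("nan")
    else:
        cc_half = float("nan")
        r_split = float("nan")

    merged = agg.reset_index().rename(columns={"hu": "h", "ku": "k", "lu": "l", "n": "multiplicity"})
    merged = merged[["h", "k", "l", "I", "sigma", "multiplicity"]]

    comp = float("nan")
    if cell is not None and d_min is not None:
        observed = merged[["h", "k", "l"]].to_numpy(int)
        comp = completeness(observed, cell, laue_group, d_min)

    stats = MergeStats(
        r_merge=r_merge,
        r_meas=r_meas,
        r_pim=r_pim,
        r_split=r_split,
        cc_half=cc_half,
        completeness=comp,
        mean_multiplicity=float(n_u.mean()),
        n_unique=int(len(agg)),
        n_observations=int(len(df)),
        d_min=d_min,
    )
    return merged, stats


def completeness(
    observed_hkl: np.ndarray, cell: UnitCell, laue_group: str, d_min: float
) -> float:
    """Fraction of expected Laue-unique reflections observed at least once."""
    expected = symmetry.enumerate_unique_reflections(cell, laue_group, d_min)
    if len(expected) == 0:
        warnings.warn(f"no reflections expected at d_min={d_min} for this cell")
        return float("nan")
    observed = symmetry.unique_hkl(np.atleast_2d(np.asarray(observed_hkl, int)), laue_group)
    exp_set = {tuple(r) for r in expected}
    obs_set = {tuple(r) for r in observed} & exp_set
    return len(obs_set) / len(exp_set)


# ---------------------------------------------------------------------------
# SHELX HKLF4 export

def write_hkl(refls: pd.DataFrame, path: str | Path) -> Path:
    """Write reflections as fixed-width SHELX HKLF4 records (3I4, 2F8.2).

    Intensities are globally rescaled when any value would overflow the
    field; the file ends with the 0 0 0 terminator record.
    """
    path = Path(path)
    if len(refls) == 0:
        warnings.warn(f"writing empty reflection file {path}")
        path.write_text("   0   0   0    0.00    0.00\n")
        return path
    hkl = refls[["h", "k", "l"]].to_numpy(int)
    if np.abs(hkl).max() > 999:
        raise InvalidArgumentError("hkl indices outside ±999 cannot be written in HKLF4")
    intensity = refls["I"].to_numpy(float)
    sigma = refls["sigma"].to_numpy(float)
    if not (np.all(np.isfinite(intensity)) and np.all(np.isfinite(sigma))):
        raise InvalidArgumentError("non-finite intensities cannot be written")
    biggest = max(np.abs(intensity).max(), np.abs(sigma).max())
    scale = 1.0
    if biggest > 99999.99:
        scale = 99999.99 / biggest
        logger.warning("rescaling intensities by %.3g to fit HKLF4 fields", scale)
    with open(path, "w") as fh:
        for (h, k, l), iv, sv in zip(hkl, intensity * scale, sigma * scale):
            fh.write(f"{h:4d}{k:4d}{l:4d}{iv:8.2f}{sv:8.2f}\n")
        fh.write("   0   0   0    0.00    0.00\n")
    return path


def read_hkl(path: str | Path) -> pd.DataFrame:
    """Parse an HKLF4 file back into (h, k, l, I, sigma)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if len(line) < 28:
            continue
        h, k, l = int(line[0:4]), int(line[4:8]), int(line[8:12])
        if h == k == l == 0:
            break
        rows.append({"h": h, "k": k, "l": l, "I": float(line[12:20]), "sigma": float(line[20:28])})
    return pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma"])
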