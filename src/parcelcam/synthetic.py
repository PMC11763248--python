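"""Synthetic cohorts with the statistical structure of a longitudinal AD study.

The generators emulate the features of the study cohort that the pipeline's
correctness depends on, without any imaging download:

* two classes (AD / HC) with imbalanced session counts — the default session
  imbalance mirrors an HC:AD ratio of 557:135;
* multiple sessions per subject (mean ~1.27 sessions);
* a small fraction of subjects (default 2.76%) whose class changes between
  sessions, so subject-exclusive splitting and the dual-class refinement
  rules are exercised;
* a class effect planted in a configurable subset of parcels — volumes: a
  fractional reduction of mean parcel intensity (an atrophy proxy);
  connectomes: attenuation of edges inside a designated subnetwork (a
  disconnection proxy).

Everything is deterministic given the seed carried by :class:`EffectSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation, ConnectivityGraph, VolumeScan, default_parcel_table

__all__ = [
    "EffectSpec",
    "Session",
    "CohortDataset",
    "make_synthetic_atlas",
    "simulate_volume_cohort",
    "simulate_graph_cohort",
    "OASIS_SESSION_RATIO",
    "DUAL_CLASS_FRACTION",
]

# session-count imbalance and dual-class subject fraction of the study cohort
OASIS_SESSION_RATIO = (557, 135)  # HC : AD sessions
DUAL_CLASS_FRACTION = 0.0276
# multi-session probabilities for 1, 2, 3 sessions (mean ~1.27, as in a
# longitudinal cohort with ~1.27 sessions per participant)
DEFAULT_SESSION_PROBS = (0.76, 0.21, 0.03)


@dataclass(frozen=True)
class EffectSpec:
    """Planted class effect: which parcels, how strong, how noisy."""

    effect_parcels: frozenset[int] = frozenset()
    effect_size: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect_size < 1.0):
            raise ValueError("effect_size must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "effect_parcels", frozenset(int(p) for p in self.effect_parcels))


@dataclass
class Session:
    subject_id: str
    session_id: str
    label: str  # "AD" or "HC"
    payload: VolumeScan | ConnectivityGraph | None = None


@dataclass
class CohortDataset:
    sessions: list[Session]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.session_id for s in self.sessions]
        if len(set(ids)) != len(ids):
            raise ValueError("session ids must be unique")
        bad = {s.label for s in self.sessions} - {"AD", "HC"}
        if bad:
            raise ValueError(f"labels must be AD or HC, got {bad}")

    @property
    def class_counts(self) -> dict[str, int]:
        out = {"HC": 0, "AD": 0}
        for s in self.sessions:
            out[s.label] += 1
        return out

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sessions:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def session_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.sessions],
                "session_id": [s.session_id for s in self.sessions],
                "label": [s.label for s in self.sessions],
            }
        )


# ---------------------------------------------------------------------------
# synthetic atlas

def _grid_dims(n_parcels: int, shape: Sequence[int]) -> tuple[int, int, int]:
    """Smallest per-axis block grid hosting at least n_parcels blocks."""
    shape = tuple(int(s) for s in shape)
    dims = [min(shape[0], max(1, round(n_parcels ** (1 / 3))))]
    rem = -(-n_parcels // dims[0])
    dims.append(min(shape[1], max(1, round(rem ** 0.5))))
    dims.append(min(shape[2], -(-rem // dims[1])))
    # grow greedily if capping at the axis size left too few blocks
    while dims[0] * dims[1] * dims[2] < n_parcels:
        grew = False
        for ax in np.argsort(dims):
            if dims[ax] < shape[ax]:
                dims[ax] += 1
                grew = True
                break
        if not grew:
            raise ValueError(
                f"cannot pack {n_parcels} non-empty blocks into shape {shape}"
            )
    return tuple(dims)


def make_synthetic_atlas(
    n_parcels: int, shape: Sequence[int] = (24, 24, 24), seed: int = 0
) -> AtlasParcellation:
    """Partition a volume into contiguous rectangular parcels.

    The volume is split into an axis-aligned grid of blocks (uneven sizes
    allowed); ``n_parcels`` blocks chosen by the seeded RNG receive labels
    1..n_parcels, the remainder stay background.  Deterministic per seed.
    """
    if n_parcels < 1:
        raise ValueError("n_parcels must be >= 1")
    shape = tuple(int(s) for s in shape)
    nx, ny, nz = _grid_dims(n_parcels, shape)
    rng = np.random.default_rng(seed)
    bx = np.array_split(np.arange(shape[0]), nx)
    by = np.array_split(np.arange(shape[1]), ny)
    bz = np.array_split(np.arange(shape[2]), nz)
    blocks = [(i, j, k) for i in range(nx) for j in range(ny) for k in range(nz)]
    order = rng.permutation(len(blocks))
    label = np.zeros(shape, dtype=np.int32)
    for pid, bidx in enumerate(order[:n_parcels], start=1):
        i, j, k = blocks[bidx]
        label[np.ix_(bx[i], by[j], bz[k])] = pid

    names = [f"Synthetic Parcel {p:03d}" for p in range(1, n_parcels + 1)]
    table = pd.DataFrame(
        {
            "parcel_id": np.arange(1, n_parcels + 1),
            "name": names,
            "hemisphere": ["midline"] * n_parcels,
            "lobe": ["synthetic"] * n_parcels,
            "group": ["cortical"] * n_parcels,
        }
    )
    return AtlasParcellation(label_volume=label, parcel_table=table)


# ---------------------------------------------------------------------------
# cohort structure (shared by both modalities)

def _draw_session_counts(
    rng: np.random.Generator,
    n_subjects: int,
    sessions_per_subject: int | Sequence[float],
    total_sessions: int | None,
) -> np.ndarray:
    if isinstance(sessions_per_subject, (int, np.integer)):
        counts = np.full(n_subjects, int(sessions_per_subject))
    else:
        probs = np.asarray(sessions_per_subject, dtype=float)
        probs = probs / probs.sum()
        counts = rng.choice(np.arange(1, len(probs) + 1), size=n_subjects, p=probs)
    if total_sessions is not None:
        # adjust counts one session at a time to hit the exact total
        counts = counts.copy()
        delta = int(total_sessions) - int(counts.sum())
        while delta != 0:
            i = rng.integers(n_subjects)
            if delta > 0 and counts[i] < 3:
                counts[i] += 1
                delta -= 1
            elif delta < 0 and counts[i] > 1:
                counts[i] -= 1
                delta += 1
    return counts


def _assign_labels(
    rng: np.random.Generator,
    counts: np.ndarray,
    class_ratio: float | tuple[int, int],
    dual_class_fraction: float,
) -> list[list[str]]:
    """Per-subject session label lists hitting a target HC:AD session split.

    ``class_ratio`` is either the HC fraction of sessions or an exact
    (n_hc_sessions, n_ad_sessions) pair.  Labels are assigned subject-wise
    (greedy, largest subjects first) so the realized split matches the target
    as closely as whole subjects allow; dual-class subjects are then created
    by flipping one session of randomly chosen multi-session subjects.
    """
    n_subjects = len(counts)
    total = int(counts.sum())
    if isinstance(class_ratio, tuple):
        n_hc, n_ad = class_ratio
        if n_hc + n_ad != total:
            raise ValueError(
                f"exact class counts {class_ratio} do not sum to {total} sessions"
            )
    else:
        frac = float(class_ratio)
        if not (0.0 < frac < 1.0):
            raise ValueError("class_ratio must leave both classes non-empty")
        n_ad = int(round((1.0 - frac) * total))
        if n_ad == 0 or n_ad == total:
            raise ValueError("class_ratio degenerate: one class is empty")
        n_hc = total - n_ad
    # greedy: fill the AD quota with whole subjects, largest first
    order = rng.permutation(n_subjects)
    order = order[np.argsort(-counts[order], kind="stable")]
    labels = [["HC"] * int(c) for c in counts]
    ad_left = n_ad
    for i in order:
        c = int(counts[i])
        if c <= ad_left:
            labels[i] = ["AD"] * c
            ad_left -= c
        if ad_left == 0:
            break
    if ad_left > 0:
        # remainder smaller than every remaining subject: flip single sessions
        for i in order:
            if labels[i][0] == "HC" and ad_left > 0:
                labels[i][0] = "AD"
                ad_left -= 1
            if ad_left == 0:
                break
    # dual-class subjects: flip one session of chosen multi-session subjects
    n_dual = int(round(dual_class_fraction * n_subjects))
    multi = [i for i in range(n_subjects) if counts[i] >= 2]
    rng.shuffle(multi)
    for i in multi[:n_dual]:
        flip_to = "AD" if labels[i][0] == "HC" else "HC"
        labels[i][-1] = flip_to
    # flips moved whole sessions between classes; restore the target session
    # split by toggling pure single-session subjects (cannot create duals)
    ad_now = sum(l.count("AD") for l in labels)
    deficit = n_ad - ad_now
    singles = [i for i in range(n_subjects) if counts[i] == 1]
    rng.shuffle(singles)
    for i in singles:
        if deficit == 0:
            break
        if deficit > 0 and labels[i] == ["HC"]:
            labels[i] = ["AD"]
            deficit -= 1
        elif deficit < 0 and labels[i] == ["AD"]:
            labels[i] = ["HC"]
            deficit += 1
    ad_now = sum(l.count("AD") for l in labels)
    if ad_now == 0 or ad_now == total:
        raise ValueError("class_ratio degenerate: one class is empty")
    return labels


def build_cohort_structure(
    rng: np.random.Generator,
    n_subjects: int,
    sessions_per_subject: int | Sequence[float],
    class_ratio: float | tuple[int, int],
    dual_class_fraction: float,
    total_sessions: int | None = None,
) -> list[Session]:
    counts = _draw_session_counts(rng, n_subjects, sessions_per_subject, total_sessions)
    labels = _assign_labels(rng, counts, class_ratio, dual_class_fraction)
    sessions: list[Session] = []
    for i in range(n_subjects):
        sid = f"sub-{i:04d}"
        for j, lab in enumerate(labels[i]):
            sessions.append(Session(sid, f"{sid}_ses-{j:02d}", lab))
    return sessions


# ---------------------------------------------------------------------------
# volume cohort

def simulate_volume_cohort(
    atlas: AtlasParcellation,
    n_subjects: int,
    sessions_per_subject: int | Sequence[float] = DEFAULT_SESSION_PROBS,
    class_ratio: float | tuple[int, int] = OASIS_SESSION_RATIO[0] / sum(OASIS_SESSION_RATIO),
    effect: EffectSpec = EffectSpec(),
    dual_class_fraction: float = DUAL_CLASS_FRACTION,
    total_sessions: int | None = None,
) -> CohortDataset:
    """Volumes with parcel-wise mean intensities and a planted atrophy effect.

    HC sessions have voxel mean mu_p inside parcel p (drawn once per cohort
    from U(0.6, 1.0); background 0); AD sessions have mean
    ``mu_p * (1 - effect_size)`` inside the effect parcels and mu_p elsewhere.
    i.i.d. Gaussian noise (sd = ``effect.noise_sd``) is added everywhere.
    """
    ids = set(int(p) for p in atlas.parcel_ids)
    if not set(effect.effect_parcels) <= ids:
        raise ValueError("effect_parcels must be a subset of atlas parcel ids")
    rng = np.random.default_rng(effect.seed)
    sessions = build_cohort_structure(
        rng, n_subjects, sessions_per_subject, class_ratio,
        dual_class_fraction, total_sessions,
    )
    mu = {int(p): rng.uniform(0.6, 1.0) for p in atlas.parcel_ids}
    base = np.zeros(atlas.label_volume.shape, dtype=float)
    for p, m in atlas.masks().items():
        base[m] = mu[p]
    effect_mask = np.isin(atlas.label_volume, list(effect.effect_parcels))
    for s in sessions:
        vox = base.copy()
        if s.label == "AD" and effect.effect_size > 0:
            vox[effect_mask] *= 1.0 - effect.effect_size
        vox += rng.normal(0.0, effect.noise_sd, size=vox.shape)
        s.payload = VolumeScan(
            voxels=vox, affine=atlas.affine,
            subject_id=s.subject_id, session_id=s.session_id, label=s.label,
        )
    prov = {
        "kind": "volume",
        "n_subjects": n_subjects,
        "class_ratio": class_ratio,
        "effect_parcels": sorted(effect.effect_parcels),
        "effect_size": effect.effect_size,
        "noise_sd": effect.noise_sd,
        "dual_class_fraction": dual_class_fraction,
        "seed": effect.seed,
    }
    return CohortDataset(sessions=sessions, provenance=prov)


# ---------------------------------------------------------------------------
# graph cohort

def simulate_graph_cohort(
    n_nodes: int,
    n_subjects: int,
    sessions_per_subject: int | Sequence[float] = DEFAULT_SESSION_PROBS,
    class_ratio: float | tuple[int, int] = OASIS_SESSION_RATIO[0] / sum(OASIS_SESSION_RATIO),
    effect: EffectSpec = EffectSpec(),
    dual_class_fraction: float = DUAL_CLASS_FRACTION,
    total_sessions: int | None = None,
    single_endpoint: bool = False,
    lognormal_sigma: float = 0.4,
) -> CohortDataset:
    """Dense symmetric connectomes with a planted subnetwork disruption.

    Each subject has a base matrix with log-normal edge weights (median 1,
    log-sd ``lognormal_sigma``); sessions add Gaussian edge noise
    (sd = ``effect.noise_sd``, clipped at 0).  For AD sessions, edges whose
    endpoints BOTH lie in ``effect.effect_parcels`` (or either endpoint, with
    ``single_endpoint=True``) are multiplied by ``1 - effect_size``.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    nodes = set(range(1, n_nodes + 1))
    if not set(effect.effect_parcels) <= nodes:
        raise ValueError("effect_parcels must be a subset of 1..n_nodes")
    rng = np.random.default_rng(effect.seed)
    sessions = build_cohort_structure(
        rng, n_subjects, sessions_per_subject, class_ratio,
        dual_class_fraction, total_sessions,
    )
    node_ids = np.arange(1, n_nodes + 1)
    in_target = np.isin(node_ids, list(effect.effect_parcels))
    if single_endpoint:
        pair_mask = np.logical_or.outer(in_target, in_target)
    else:
        pair_mask = np.logical_and.outer(in_target, in_target)
    np.fill_diagonal(pair_mask, False)
    iu = np.triu_indices(n_nodes, k=1)

    by_subject: dict[str, np.ndarray] = {}
    for s in sessions:
        if s.subject_id not in by_subject:
            w = np.zeros((n_nodes, n_nodes))
            w[iu] = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=len(iu[0]))
            by_subject[s.subject_id] = w + w.T
        base = by_subject[s.subject_id]
        m = base.copy()
        if s.label == "AD" and effect.effect_size > 0:
            m[pair_mask] *= 1.0 - effect.effect_size
        noise = np.zeros_like(m)
        noise[iu] = rng.normal(0.0, effect.noise_sd, size=len(iu[0]))
        m = np.clip(m + noise + noise.T, 0.0, None)
        np.fill_diagonal(m, 0.0)
        s.payload = ConnectivityGraph(
            matrix=m, node_ids=node_ids,
            subject_id=s.subject_id, session_id=s.session_id, label=s.label,
        )
    prov = {
        "kind": "graph",
        "n_nodes": n_nodes,
        "n_subjects": n_subjects,
        "class_ratio": class_ratio,
        "effect_parcels": sorted(effect.effect_parcels),
        "effect_size": effect.effect_size,
        "noise_sd": effect.noise_sd,
        "dual_class_fraction": dual_class_fraction,
        "single_endpoint": single_endpoint,
        "seed": effect.seed,
    }
    return CohortDataset(sessions=sessions, provenance=prov)


def oasis_like_structure(seed: int = 0) -> CohortDataset:
    """A 543-subject, 692-session cohort skeleton with the study's 557:135
    HC:AD session split and ~2.76% dual-class subjects (no payloads)."""
    rng = np.random.default_rng(seed)
    sessions = build_cohort_structure(
        rng, n_subjects=543, sessions_per_subject=DEFAULT_SESSION_PROBS,
        class_ratio=OASIS_SESSION_RATIO, dual_class_fraction=DUAL_CLASS_FRACTION,
        total_sessions=sum(OASIS_SESSION_RATIO),
    )
    return CohortDataset(sessions=sessions, provenance={"kind": "structure", "seed": seed})
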