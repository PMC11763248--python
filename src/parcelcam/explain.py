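"""Grad-CAM heatmaps, multi-layer averaging, and parcel relevance values.

For a class c with score s_c (here: the classifier logit for AD, its
negation for HC), the heatmap of one tapped layer with activation maps a_k
is

    g_c = ReLU( sum_k w_ck a_k ),     w_ck = mean over the layer grid of
                                             ds_c / da_k

computed on the layer's own grid and then resampled to the input size by
cubic interpolation per axis (negative interpolation overshoot is clipped so
the ReLU nonnegativity survives resampling).  Heatmaps from the L tapped
layers — the four stage outputs of the volume network, the three GPC-SE
blocks of the graph network — are averaged entrywise without per-layer
renormalization into the mean heatmap G_c.

The relevance value (RV) of parcel p summarizes G_c anatomically:

* volumes:  RV_{p,c} = mean of G_c over the voxels of the parcel mask M_p;
* graphs:   RV_{p,c} = mean of row p of G_c excluding the diagonal entry
            (denominator N - 1, i.e. 131 for the 132-parcel atlas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasParcellation, ConnectivityGraph, VolumeScan
from .preprocess import _resize
from .synthetic import CohortDataset

__all__ = [
    "LayerHeatmap", "MeanHeatmap",
    "gradcam_layer", "gradcam_all_layers", "mean_heatmap",
    "parcel_rv_volume", "parcel_rv_graph", "session_rv_table",
    "minmax_normalize",
]


@dataclass
class LayerHeatmap:
    values: np.ndarray  # >= 0, input-sized
    layer: str
    class_label: str
    weights: np.ndarray  # the K relevance weights w_ck, kept for audit


@dataclass
class MeanHeatmap:
    values: np.ndarray
    n_layers: int
    class_label: str


def _heatmap_from_tap(acts: np.ndarray, grads: np.ndarray,
                      out_shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """ReLU-weighted activation sum on the layer grid, resampled to out_shape."""
    k = acts.shape[0]
    w = grads.reshape(k, -1).mean(axis=1)
    raw = np.maximum(np.tensordot(w, acts, axes=1), 0.0)
    if np.all(raw == 0):
        warnings.warn("all-zero heatmap (zero gradients)", RuntimeWarning,
                      stacklevel=3)
    if raw.shape != tuple(out_shape):
        raw = _resize(raw, tuple(out_shape), order=3)
        np.clip(raw, 0.0, None, out=raw)  # cubic overshoot
    return raw, w


def _input_array(payload) -> np.ndarray:
    if isinstance(payload, VolumeScan):
        return payload.voxels
    if isinstance(payload, ConnectivityGraph):
        return payload.matrix
    return np.asarray(payload, dtype=float)


def gradcam_all_layers(model, x, class_label: str) -> list[LayerHeatmap]:
    """One input-sized heatmap per registered tap layer."""
    arr = _input_array(x)
    taps = model.gradcam_taps(arr, class_label)
    out = []
    for name, (acts, grads) in taps.items():
        values, w = _heatmap_from_tap(acts, grads, arr.shape)
        out.append(LayerHeatmap(values=values, layer=name,
                                class_label=class_label, weights=w))
    return out


def gradcam_layer(model, x, class_label: str, layer: str) -> LayerHeatmap:
    """Heatmap of a single tapped layer."""
    if layer not in model.tap_names:
        raise ValueError(
            f"layer {layer!r} is not a registered tap; taps: {model.tap_names}"
        )
    arr = _input_array(x)
    acts, grads = model.gradcam_taps(arr, class_label)[layer]
    values, w = _heatmap_from_tap(acts, grads, arr.shape)
    return LayerHeatmap(values=values, layer=layer,
                        class_label=class_label, weights=w)


def mean_heatmap(heatmaps: list[LayerHeatmap]) -> MeanHeatmap:
    """Entrywise arithmetic mean of same-class, same-shape layer heatmaps."""
    if not heatmaps:
        raise ValueError("no heatmaps to average")
    classes = {h.class_label for h in heatmaps}
    shapes = {h.values.shape for h in heatmaps}
    if len(classes) > 1:
        raise ValueError(f"mixed classes: {classes}")
    if len(shapes) > 1:
        raise ValueError(f"mixed shapes: {shapes}")
    stack = np.stack([h.values for h in heatmaps])
    return MeanHeatmap(values=stack.mean(axis=0), n_layers=len(heatmaps),
                       class_label=classes.pop())


def parcel_rv_volume(g: MeanHeatmap | np.ndarray,
                     atlas: AtlasParcellation) -> pd.Series:
    """Masked mean of the heatmap over every parcel mask."""
    values = g.values if isinstance(g, MeanHeatmap) else np.asarray(g, dtype=float)
    if values.shape != atlas.label_volume.shape:
        raise ValueError(
            f"heatmap shape {values.shape} != atlas shape {atlas.label_volume.shape}"
        )
    out = {}
    for p in atlas.parcel_ids:
        m = atlas.mask(p)
        size = int(m.sum())
        if size == 0:
            raise ValueError(f"parcel {int(p)} has an empty mask")
        out[int(p)] = float(values[m].sum() / size)
    return pd.Series(out, name="rv").rename_axis("parcel_id")


def parcel_rv_graph(g: MeanHeatmap | np.ndarray,
                    node_ids: np.ndarray | None = None,
                    symmetrize: bool = False) -> pd.Series:
    """Off-diagonal row mean of the heatmap for every node (denominator N-1)."""
    values = g.values if isinstance(g, MeanHeatmap) else np.asarray(g, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square heatmap, got {values.shape}")
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if symmetrize:
        values = 0.5 * (values + values.T)
    rv = (values.sum(axis=1) - np.diag(values)) / (n - 1)
    if node_ids is None:
        node_ids = np.arange(1, n + 1)
    return pd.Series(rv, index=pd.Index(np.asarray(node_ids, dtype=int),
                                        name="parcel_id"), name="rv")


def session_rv_table(model, cohort: CohortDataset,
                     atlas: AtlasParcellation | None = None,
                     classes: tuple[str, ...] = ("AD", "HC"),
                     symmetrize: bool = False) -> pd.DataFrame:
    """Relevance-value table for every session and attribution class.

    Volumes need ``atlas`` (masks on the model input grid); graphs derive
    node-wise RVs directly from the square heatmap.
    """
    rows = []
    for s in cohort.sessions:
        for c in classes:
            hm = mean_heatmap(gradcam_all_layers(model, s.payload, c))
            if isinstance(s.payload, ConnectivityGraph):
                rv = parcel_rv_graph(hm, node_ids=s.payload.node_ids,
                                     symmetrize=symmetrize)
            else:
                if atlas is None:
                    raise ValueError("volume RV aggregation requires an atlas")
                rv = parcel_rv_volume(hm, atlas)
            for p, v in rv.items():
                rows.append((s.session_id, s.subject_id, c, int(p), float(v)))
    return pd.DataFrame(
        rows, columns=["session_id", "subject_id", "class_label", "parcel_id", "rv"]
    )


def minmax_normalize(table: pd.DataFrame,
                     correct_session_ids: set[str] | None = None) -> pd.DataFrame:
    """Min-max rescale RVs to [0, 1] for reporting (never fed to statistics).

    The extremes are taken across every parcel of every (optionally: every
    correctly classified) session in the table.
    """
    sub = table if correct_session_ids is None else table[
        table["session_id"].isin(correct_session_ids)
    ]
    if sub.empty:
        raise ValueError("normalization scope is empty")
    lo, hi = sub["rv"].min(), sub["rv"].max()
    if hi == lo:
        raise ValueError("degenerate normalization scope: max equals min")
    out = sub.copy()
    out["rv"] = (sub["rv"] - lo) / (hi - lo)
    return out
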