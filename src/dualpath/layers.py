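"""Radial-layer analysis of straightened-axis cell maps and morphologies.

Cell coordinates (radial in [0,1], 0 = alveus side; longitudinal in [0,1]
along the straightened CA3->subiculum field) are clustered with full
covariance Gaussian mixtures for k = 1..6; BIC selects the component count.
With k = 2 the component whose radial mean is nearer the alveus is named
"deep" and the other "superficial"; tracer-flagged subsets are then assigned
to layers by maximum posterior.  SWC morphologies are summarized by
reference-line Sholl profiles and soma-relative metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.mixture import GaussianMixture

__all__ = [
    "CellMap",
    "LayerModel",
    "Morphology",
    "intensity_profile",
    "fit_layer_gmm",
    "assign_layers",
    "subset_layer_fractions",
    "colocalization",
    "sholl_from_reference",
    "morph_metrics",
]

_COORD_COLS = ("radial", "longitudinal")


@dataclass
class CellMap:
    """Table of cells with normalized coordinates and boolean tracer flags."""

    cells: pd.DataFrame
    tracer_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.cells
        for col in _COORD_COLS:
            if col not in df.columns:
                raise ValueError(f"cell map missing {col!r} column")
            vals = df[col].to_numpy(dtype=float)
            if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError(f"{col} coordinates must lie in [0, 1]")
        for flag in self.tracer_flags:
            if flag not in df.columns:
                raise ValueError(f"cell map missing tracer column {flag!r}")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[list(_COORD_COLS)].to_numpy(dtype=float)


def intensity_profile(
    cellmap: CellMap,
    axis: str = "radial",
    bin_width: float = 0.02,
    smoothing: float = 0.03,
) -> pd.DataFrame:
    """Peak-normalized (optionally Gaussian-smoothed) cell-density profile.

    Returns a frame with bin centres and the profile normalized to max 1.
    ``smoothing`` is the Gaussian kernel SD in coordinate units (0 disables).
    """
    if axis not in _COORD_COLS:
        raise ValueError(f"axis must be one of {_COORD_COLS}")
    if len(cellmap) == 0:
        raise ValueError("cannot profile an empty cell map")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    hist, _ = np.histogram(cellmap.cells[axis].to_numpy(dtype=float), bins=edges)
    prof = hist.astype(float)
    if smoothing > 0:
        prof = gaussian_filter1d(prof, sigma=smoothing / bin_width, mode="nearest")
    peak = prof.max()
    if peak > 0:
        prof /= peak
    centres = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"position": centres, "intensity": prof})


@dataclass
class LayerModel:
    """Candidate mixtures per component count with BIC-based selection."""

    ks: tuple[int, ...]
    models: dict[int, GaussianMixture]
    bics: dict[int, float]
    converged: dict[int, bool]
    selected_k: int
    n_cells: int

    #: BIC ties within this margin are broken toward the smaller k
    TIE_TOL = 1e-6

    @property
    def selected(self) -> GaussianMixture:
        return self.models[self.selected_k]

    def layer_names(self) -> dict[int, str]:
        """Component-index -> layer-name map (only defined for k = 2).

        The component with the radial mean nearest 0 (the alveus side) is
        "deep"; the other is "superficial".
        """
        if self.selected_k != 2:
            raise ValueError(
                f"layer naming requires k = 2 (selected k = {self.selected_k}); "
                "use component indices instead"
            )
        means = self.selected.means_[:, 0]
        deep_idx = int(np.argmin(means))
        return {deep_idx: "deep", 1 - deep_idx: "superficial"}


def fit_layer_gmm(
    cellmap: CellMap,
    k_range=range(1, 7),
    n_init: int = 10,
    seed: int = 0,
) -> LayerModel:
    """Fit full-covariance mixtures over (radial, longitudinal) for each k.

    BIC (= -2 logL + p ln n) is recorded per candidate; the selected k
    minimizes BIC, with ties (within 1e-6) broken toward smaller k.
    Non-converged candidates are flagged and excluded from selection.
    """
    ks = tuple(int(k) for k in k_range)
    x = cellmap.coords
    if len(cellmap) < 2 * max(ks):
        raise ValueError(f"need at least {2 * max(ks)} cells to consider k up to {max(ks)}")
    models: dict[int, GaussianMixture] = {}
    bics: dict[int, float] = {}
    converged: dict[int, bool] = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="k-means++",
            tol=1e-4,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        models[k] = gm
        converged[k] = bool(gm.converged_)
        bics[k] = float(gm.bic(x)) if gm.converged_ else float("nan")
    usable = [k for k in ks if converged[k] and np.isfinite(bics[k])]
    if not usable:
        raise RuntimeError("no mixture candidate converged")
    best = usable[0]
    for k in usable[1:]:
        if bics[k] < bics[best] - LayerModel.TIE_TOL:
            best = k
    return LayerModel(
        ks=ks, models=models, bics=bics, converged=converged,
        selected_k=best, n_cells=len(cellmap),
    )


def assign_layers(model: LayerModel, cellmap: CellMap, use_names: bool = True) -> pd.DataFrame:
    """Maximum-posterior component assignment per cell.

    Returns the cell table augmented with ``component``, ``posterior`` and —
    when the selected k is 2 and ``use_names`` — a ``layer`` column
    (deep/superficial per the radial-mean ordering).
    """
    x = cellmap.coords
    resp = model.selected.predict_proba(x)
    comp = resp.argmax(axis=1)
    out = cellmap.cells.copy()
    out["component"] = comp
    out["posterior"] = resp[np.arange(len(comp)), comp]
    if use_names:
        names = model.layer_names()  # raises for k != 2
        out["layer"] = [names[c] for c in comp]
    return out


def subset_layer_fractions(assignments: pd.DataFrame, flag: str) -> dict:
    """Fraction of ``flag``-positive cells in each layer, pooled and per slice."""
    if flag not in assignments.columns:
        raise ValueError(f"no tracer column {flag!r}")
    if "layer" not in assignments.columns:
        raise ValueError("assignments need a 'layer' column (run assign_layers)")
    sub = assignments[assignments[flag].astype(bool)]
    if sub.empty:
        warnings.warn(f"no {flag}-positive cells; fractions are NaN", stacklevel=2)
        pooled = pd.Series({"deep": float("nan"), "superficial": float("nan")})
        return {"pooled": pooled, "per_slice": pd.DataFrame()}
    pooled = sub["layer"].value_counts(normalize=True).reindex(
        ["deep", "superficial"], fill_value=0.0
    )
    per_slice = pd.DataFrame()
    if "slice" in sub.columns:
        per_slice = (
            sub.groupby("slice")["layer"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=["deep", "superficial"], fill_value=0.0)
        )
    return {"pooled": pooled, "per_slice": per_slice}


def colocalization(
    cellmap: CellMap,
    flag_a: str,
    flag_b: str,
    assignments: pd.DataFrame | None = None,
) -> dict:
    """Dual-labelled fraction: |A and B| over the union, plus per-flag bases.

    If ``assignments`` (with a ``layer`` column) is given, the per-layer
    split of dual-labelled cells is included.
    """
    df = assignments if assignments is not None else cellmap.cells
    for flag in (flag_a, flag_b):
        if flag not in df.columns:
            raise ValueError(f"no tracer column {flag!r}")
    a = df[flag_a].astype(bool).to_numpy()
    b = df[flag_b].astype(bool).to_numpy()
    dual = a & b
    union = a | b
    out = {
        "n_dual": int(dual.sum()),
        "dual_over_union": float(dual.sum() / union.sum()) if union.sum() else float("nan"),
        "dual_over_a": float(dual.sum() / a.sum()) if a.sum() else float("nan"),
        "dual_over_b": float(dual.sum() / b.sum()) if b.sum() else float("nan"),
    }
    if assignments is not None and "layer" in df.columns and dual.sum():
        split = df.loc[dual, "layer"].value_counts(normalize=True)
        out["dual_layer_split"] = split.reindex(["deep", "superficial"], fill_value=0.0)
    return out


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

#: SWC structure identifiers for dendrites
SWC_BASAL = 3
SWC_APICAL = 4
SWC_SOMA = 1


@dataclass
class Morphology:
    """SWC tree plus the alveus reference line used for Sholl-style binning."""

    nodes: pd.DataFrame  # columns: id, type, x, y, z, radius, parent
    reference_line: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        req = {"id", "type", "x", "y", "z", "radius", "parent"}
        missing = req - set(self.nodes.columns)
        if missing:
            raise ValueError(f"morphology table missing columns {sorted(missing)}")
        ids = self.nodes["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SWC node ids")
        roots = self.nodes[self.nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root node, found {len(roots)}")
        seen: set[int] = set()
        for nid, parent in zip(ids, self.nodes["parent"].to_numpy()):
            if parent != -1 and parent not in seen:
                raise ValueError(f"node {nid}: parent {parent} does not precede it (cycle or bad order)")
            seen.add(nid)

    @property
    def soma(self) -> pd.Series:
        return self.nodes[self.nodes["parent"] == -1].iloc[0]

    def children_of(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {}
        for nid, parent in zip(self.nodes["id"], self.nodes["parent"]):
            if parent != -1:
                kids.setdefault(int(parent), []).append(int(nid))
        return kids


def _point_line_distance(px: np.ndarray, py: np.ndarray, line) -> np.ndarray:
    (x1, y1), (x2, y2) = line
    dx, dy = x2 - x1, y2 - y1
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        raise ValueError("degenerate reference line")
    return np.abs(dx * (py - y1) - dy * (px - x1)) / norm


def sholl_from_reference(morph: Morphology, bin_width: float = 10.0) -> pd.DataFrame:
    """Dendritic length per distance-from-alveus bin, apical/basal separated.

    Each parent->child segment's 3-D length is accumulated into the bin of
    its midpoint's perpendicular (x, y) distance from the reference line.
    """
    if morph.reference_line is None:
        raise ValueError("morphology has no reference line")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nodes = morph.nodes.set_index("id")
    seg_rows = []
    for _, node in morph.nodes.iterrows():
        if node["parent"] == -1 or node["type"] not in (SWC_BASAL, SWC_APICAL):
            continue
        parent = nodes.loc[node["parent"]]
        length = float(
            np.sqrt(
                (node["x"] - parent["x"]) ** 2
                + (node["y"] - parent["y"]) ** 2
                + (node["z"] - parent["z"]) ** 2
            )
        )
        mx, my = (node["x"] + parent["x"]) / 2, (node["y"] + parent["y"]) / 2
        seg_rows.append((node["type"], mx, my, length))
    if not seg_rows:
        return pd.DataFrame(columns=["bin_start", "bin_end", "apical", "basal"])
    seg = pd.DataFrame(seg_rows, columns=["type", "mx", "my", "length"])
    seg["dist"] = _point_line_distance(
        seg["mx"].to_numpy(), seg["my"].to_numpy(), morph.reference_line
    )
    n_bins = int(np.floor(seg["dist"].max() / bin_width)) + 1
    out = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": (np.arange(n_bins) + 1) * bin_width,
            "apical": 0.0,
            "basal": 0.0,
        }
    )
    seg["bin"] = np.minimum((seg["dist"] // bin_width).astype(int), n_bins - 1)
    for comp, swc_type in (("apical", SWC_APICAL), ("basal", SWC_BASAL)):
        sums = seg[seg["type"] == swc_type].groupby("bin")["length"].sum()
        out.loc[sums.index, comp] = sums.to_numpy()
    return out


def morph_metrics(morph: Morphology) -> dict:
    """Farthest dendritic tip (Euclidean from soma) and apical bifurcation
    path distance from soma; the latter is NaN when the apical trunk never
    branches."""
    nodes = morph.nodes.set_index("id")
    soma = morph.soma
    kids = morph.children_of()

    tips = [
        nid
        for nid in morph.nodes["id"]
        if int(nid) not in kids and nodes.loc[nid, "type"] in (SWC_BASAL, SWC_APICAL)
    ]
    if tips:
        tip_xyz = nodes.loc[tips, ["x", "y", "z"]].to_numpy(dtype=float)
        d = np.sqrt(((tip_xyz - soma[["x", "y", "z"]].to_numpy(dtype=float)) ** 2).sum(axis=1))
        farthest = float(d.max())
    else:
        farthest = float("nan")

    # path length from soma to the first apical node with >= 2 children
    path_len = {int(soma["id"]): 0.0}
    stack = [int(soma["id"])]
    bifurcation = float("nan")
    best = np.inf
    while stack:
        nid = stack.pop()
        for child in kids.get(nid, []):
            crow, prow = nodes.loc[child], nodes.loc[nid]
            step = float(
                np.sqrt(
                    (crow["x"] - prow["x"]) ** 2
                    + (crow["y"] - prow["y"]) ** 2
                    + (crow["z"] - prow["z"]) ** 2
                )
            )
            path_len[child] = path_len[nid] + step
            stack.append(child)
            if crow["type"] == SWC_APICAL and len(kids.get(child, [])) >= 2:
                if path_len[child] < best:
                    best = path_len[child]
                    bifurcation = path_len[child]
    return {
        "farthest_tip_um": farthest,
        "apical_bifurcation_um": bifurcation,
        "has_apical_bifurcation": np.isfinite(bifurcation),
    }
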