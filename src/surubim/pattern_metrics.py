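"""Morphometry of steady patterns: motifs, region classes, phase diagram.

The visible pattern of a steady outer-layer state is its dark-pigment
phase, the region of morphogen *deficiency* (``pigment_phase(u2) = -u2``;
the morphogen inhibits melanophore proliferation).  That field is
thresholded at its natural datum (zero: the fields measure deviation from
an average level) and the foreground connected components are classified
into the three basic motifs seen on surubim skin:

* **cell** -- a closed loop enclosing lighter interior: a component with at
  least one hole;
* **stripe** -- an elongated hole-free component (labyrinth meanders are
  grouped here too);
* **dot** -- everything else: a compact spot, not necessarily circular.

Counting motifs over a field yields a :class:`PatternSummary` with one of
four qualitative region classes: (1) only cells, (2) cells plus dots and
stripes, (3) dots and stripes, (4) only dots.  Sweeping the outer-layer
level ``u02`` against the inter-layer coupling ``q`` and classifying each
steady state reconstructs the two-parameter phase diagram whose regions
host the patterns of the different species.

The morphometric cutoffs (threshold, minimum area, elongation, region
fractions) are explicit configuration, not constants: the region taxonomy
is qualitative and the cutoffs are this package's operational stand-ins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.measure import label as _label
from skimage.measure import perimeter as _perimeter
from skimage.measure import regionprops

from .init_conditions import build_initial_state
from .simulator import BlowUpError, CouplingParams, simulate

__all__ = [
    "ComponentStats",
    "MotifThresholds",
    "PatternSummary",
    "PhaseDiagram",
    "binarize",
    "component_stats",
    "classify_motif",
    "summarize_pattern",
    "pigment_phase",
    "phase_sweep",
    "disk_mask",
    "annulus_mask",
    "bar_mask",
]

logger = logging.getLogger(__name__)

MOTIFS = ("dot", "stripe", "cell")


@dataclass(frozen=True)
class MotifThresholds:
    """Cutoffs of the motif and region classifiers.

    threshold
        Binarisation level; 0 is the natural datum of a deviation field.
    min_area
        Components smaller than this many cells are discarded as noise.
    elongation_cutoff
        Major/minor axis ratio separating stripes from dots.
    compactness_cutoff
        Components with isoperimetric compactness ``4*pi*area/perimeter**2``
        at or below this are stripes regardless of elongation: the best-fit
        ellipse of a branched or space-filling labyrinth is nearly round,
        so thinness, which is scale-invariant, catches what elongation
        misses.
    fill_cutoff
        A hole-free component covering at least this fraction of the
        domain is a uniform sea, not a motif; it is dropped (a sea *with*
        holes is kept -- that is the closed-loop "cell" structure).
    pure_fraction
        Fraction of components of a single motif above which a pattern
        counts as "only cells" (class 1) or "only dots" (class 4).
    mixed_cell_fraction
        Minimum cell fraction for the mixed class 2 when all three motifs
        are present.
    """

    threshold: float = 0.0
    min_area: int = 5
    elongation_cutoff: float = 3.0
    compactness_cutoff: float = 0.35
    fill_cutoff: float = 0.97
    pure_fraction: float = 0.8
    mixed_cell_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.elongation_cutoff < 1:
            raise ValueError("elongation_cutoff must be >= 1")
        if not 0 < self.compactness_cutoff < 1:
            raise ValueError("compactness_cutoff must be in (0, 1)")
        if not 0 < self.fill_cutoff <= 1:
            raise ValueError("fill_cutoff must be in (0, 1]")
        if not 0 < self.pure_fraction <= 1:
            raise ValueError("pure_fraction must be in (0, 1]")
        if not 0 <= self.mixed_cell_fraction <= 1:
            raise ValueError("mixed_cell_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ComponentStats:
    """Shape descriptors of one foreground connected component.

    ``compactness`` is the isoperimetric ratio ``4*pi*area/perimeter**2``
    (~1 for a disk, small for thin or branched shapes; invariant under
    integer upscaling).  ``filled_compactness`` is the same ratio after
    filling the holes: it separates a shape that is thin *because* it
    encloses loops (an annulus fills to a compact disk) from one whose
    backbone itself meanders (a labyrinth stays thin when filled).
    """

    area: int
    perimeter: float
    n_holes: int
    elongation: float
    compactness: float
    filled_compactness: float
    touches_boundary: bool

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("component area must be >= 1")
        if self.n_holes < 0:
            raise ValueError("n_holes must be >= 0")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.compactness < 0:
            raise ValueError("compactness must be >= 0")


@dataclass(frozen=True)
class PatternSummary:
    """Motif counts, fractions and the qualitative region class.

    ``region_class`` is 1-4 per the taxonomy in the module docstring, or
    ``None`` when no component survives the area filter (``featureless``).
    """

    n_dots: int
    n_stripes: int
    n_cells: int
    dot_fraction: float
    stripe_fraction: float
    cell_fraction: float
    region_class: int | None
    featureless: bool

    @property
    def n_components(self) -> int:
        return self.n_dots + self.n_stripes + self.n_cells


def binarize(fld: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Foreground mask: cells where the field exceeds ``threshold``."""
    return np.asarray(fld) > threshold


def component_stats(mask: np.ndarray) -> list[ComponentStats]:
    """Per-component shape statistics of a binary mask.

    Foreground components are 8-connected (holes therefore 4-connected,
    the matching dual); holes are counted as ``1 - Euler number``.
    Components touching the domain boundary are kept but flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    lbl = _label(mask, connectivity=2)
    ny, nx = mask.shape
    out = []
    for rp in regionprops(lbl):
        minor = rp.axis_minor_length
        elong = float(rp.axis_major_length / minor) if minor > 0 else np.inf
        perim = float(rp.perimeter)
        compact = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 1.0
        n_holes = max(0, 1 - int(rp.euler_number))
        if n_holes == 0:
            filled_compact = compact
        else:
            fperim = float(_perimeter(rp.image_filled, neighborhood=4))
            filled_compact = (
                4.0 * np.pi * rp.area_filled / fperim**2 if fperim > 0 else 1.0
            )
        r0, c0, r1, c1 = rp.bbox
        out.append(
            ComponentStats(
                area=int(rp.area),
                perimeter=perim,
                n_holes=n_holes,
                elongation=max(1.0, elong),
                compactness=float(compact),
                filled_compactness=float(filled_compact),
                touches_boundary=(r0 == 0 or c0 == 0 or r1 == ny or c1 == nx),
            )
        )
    return out


def classify_motif(
    cs: ComponentStats, thresholds: MotifThresholds = MotifThresholds()
) -> str:
    """Label one component: cell, stripe or dot.

    Holes are the defining topology of a cell (a closed pigment loop);
    among hole-free components, elongated *or* thin/branched ones (low
    compactness -- labyrinth meanders) are stripes; the rest are dots.
    """
    if cs.n_holes >= 1:
        return "cell"
    if (
        cs.elongation >= thresholds.elongation_cutoff
        or cs.compactness <= thresholds.compactness_cutoff
    ):
        return "stripe"
    return "dot"


def _region_class(nd: int, ns: int, nc: int, thr: MotifThresholds) -> int:
    total = nd + ns + nc
    if nc / total >= thr.pure_fraction:
        return 1
    if nd / total >= thr.pure_fraction:
        return 4
    if nd > 0 and ns > 0 and nc > 0 and nc / total >= thr.mixed_cell_fraction:
        return 2
    return 3


def pigment_phase(u2: np.ndarray) -> np.ndarray:
    """The visible dark-pigment field of an outer-layer state: ``-u2``.

    The morphogen level ``u`` acts as an inhibitor of melanophore
    proliferation, so melanophore-dense (dark) skin sits where the outer
    layer shows a morphogen *deficiency*.  Negating ``u2`` makes the dark
    phase the foreground of the thresholded mask, so that motif counting
    operates on the pattern actually seen on the fish.
    """
    return -np.asarray(u2, dtype=float)


def summarize_pattern(
    fld: np.ndarray, thresholds: MotifThresholds = MotifThresholds()
) -> PatternSummary:
    """Classify a steady field into motif counts and a region class.

    ``fld`` is the field whose super-threshold phase is the pattern of
    interest (for an outer-layer state, pass ``pigment_phase(u2)``).
    A hole-free component filling essentially the whole domain (fraction
    >= ``fill_cutoff``) is a uniform sea and does not count as a motif, so
    a homogeneous steady state comes out featureless.
    """
    fld = np.asarray(fld, dtype=float)
    if not np.all(np.isfinite(fld)):
        raise ValueError("field contains non-finite values")
    stats = [
        cs
        for cs in component_stats(binarize(fld, thresholds.threshold))
        if cs.area >= thresholds.min_area
        and not (cs.n_holes == 0 and cs.area >= thresholds.fill_cutoff * fld.size)
    ]
    # dots and stripes count one per component; a cell-labelled component
    # counts one per enclosed loop: on reticulated skins the loops share
    # walls, so a single connected network carries many closed cells.  A
    # holey component that is itself thin or elongated is a labyrinth
    # carrying loops, so its stripe backbone is counted as well.
    nd = ns = nc = 0
    for cs in stats:
        motif = classify_motif(cs, thresholds)
        if motif == "dot":
            nd += 1
        elif motif == "stripe":
            ns += 1
        else:
            nc += cs.n_holes
            # the backbone of a holey component is judged with its holes
            # filled: an annulus fills to a compact disk (no stripe), a
            # loop-carrying labyrinth stays thin when filled (stripe too)
            if (
                cs.elongation >= thresholds.elongation_cutoff
                or cs.filled_compactness <= thresholds.compactness_cutoff
            ):
                ns += 1
    total = nd + ns + nc
    if total == 0:
        return PatternSummary(0, 0, 0, 0.0, 0.0, 0.0, None, True)
    return PatternSummary(
        n_dots=nd,
        n_stripes=ns,
        n_cells=nc,
        dot_fraction=nd / total,
        stripe_fraction=ns / total,
        cell_fraction=nc / total,
        region_class=_region_class(nd, ns, nc, thresholds),
        featureless=False,
    )


@dataclass
class PhaseDiagram:
    """Region class per (u02, q) cell of a sweep.

    ``region_class[i, j]`` corresponds to ``q_values[i]``, ``u02_values[j]``
    (0 marks a cell where every run failed or was featureless).
    ``summaries[(u02, q)]`` holds one :class:`PatternSummary` (or ``None``
    on blow-up) per seed; ``failures`` maps ``(u02, q, seed)`` to the error
    message of a diverged run.
    """

    u02_values: np.ndarray
    q_values: np.ndarray
    seeds: list
    region_class: np.ndarray
    summaries: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)

    def class_at(self, u02: float, q: float) -> int:
        j = int(np.argmin(np.abs(self.u02_values - u02)))
        i = int(np.argmin(np.abs(self.q_values - q)))
        return int(self.region_class[i, j])

    def to_frame(self):
        """One row per (u02, q, seed) as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for (u02, q), per_seed in self.summaries.items():
            for seed, s in zip(self.seeds, per_seed):
                row = {"u02": u02, "q": q, "seed": seed}
                if s is None:
                    row.update(
                        failed=True, region_class=0,
                        n_dots=np.nan, n_stripes=np.nan, n_cells=np.nan,
                        dot_fraction=np.nan, stripe_fraction=np.nan,
                        cell_fraction=np.nan,
                    )
                else:
                    row.update(
                        failed=False,
                        region_class=s.region_class or 0,
                        n_dots=s.n_dots, n_stripes=s.n_stripes,
                        n_cells=s.n_cells, dot_fraction=s.dot_fraction,
                        stripe_fraction=s.stripe_fraction,
                        cell_fraction=s.cell_fraction,
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def _modal_class(summaries: list) -> int:
    classes = [s.region_class for s in summaries if s is not None and s.region_class]
    if not classes:
        return 0
    return int(np.bincount(classes).argmax())  # ties -> lowest class


def phase_sweep(
    u02_values,
    q_values,
    base_config,
    n_seeds: int = 1,
) -> PhaseDiagram:
    """Map the (u02, q) plane to region classes.

    For each grid cell the initial state is rebuilt with the cell's
    ``u02``, integrated with the cell's ``q`` and the steady ``u2`` field
    summarised.  With the default single seed every cell shares the same
    initial random conditions; with ``n_seeds > 1`` consecutive seeds are
    run and the modal region class is kept (ties break to the lowest
    class), which stabilises cells near the smooth region boundaries.
    Diverged runs are recorded per-cell, never fatal to the sweep.

    ``base_config`` supplies everything except (u02, q): any object with
    attributes ``kinetics1``, ``kinetics2``, ``grid``, ``prepattern``,
    ``init``, ``integration`` and ``thresholds`` (e.g. a ``RunConfig``).
    """
    u02_values = np.asarray(list(u02_values), dtype=float)
    q_values = np.asarray(list(q_values), dtype=float)
    if u02_values.size == 0 or q_values.size == 0:
        raise ValueError("sweep axes must be non-empty")
    seeds = [base_config.init.seed + i for i in range(n_seeds)]
    region = np.zeros((q_values.size, u02_values.size), dtype=int)
    summaries: dict = {}
    failures: dict = {}
    for i, q in enumerate(q_values):
        coupling = CouplingParams(float(q))
        for j, u02 in enumerate(u02_values):
            per_seed = []
            for seed in seeds:
                init = replace(base_config.init, u02=float(u02), seed=seed)
                state0 = build_initial_state(
                    base_config.grid, base_config.prepattern, init
                )
                try:
                    res = simulate(
                        state0,
                        base_config.kinetics1,
                        base_config.kinetics2,
                        coupling,
                        base_config.integration,
                        base_config.grid,
                    )
                except BlowUpError as exc:
                    failures[(float(u02), float(q), seed)] = str(exc)
                    per_seed.append(None)
                    continue
                per_seed.append(
                    summarize_pattern(
                        pigment_phase(res.final.u2), base_config.thresholds
                    )
                )
            summaries[(float(u02), float(q))] = per_seed
            region[i, j] = _modal_class(per_seed)
            logger.info(
                "sweep cell u02=%g q=%g -> class %d", u02, q, region[i, j]
            )
    return PhaseDiagram(
        u02_values=u02_values,
        q_values=q_values,
        seeds=seeds,
        region_class=region,
        summaries=summaries,
        failures=failures,
    )


# --- synthetic shape fixtures -------------------------------------------
# Small binary masks with known topology, used to pin down the motif
# classifier (and exported by the CLI for visual checks).


def disk_mask(radius: int = 10, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Filled disk: one component, no holes, elongation ~1 (a dot)."""
    if shape is None:
        shape = (2 * radius + 5, 2 * radius + 5)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def annulus_mask(
    outer: int = 12, inner: int = 6, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Ring: one component with one hole (a cell)."""
    if inner >= outer:
        raise ValueError("inner radius must be smaller than outer")
    if shape is None:
        shape = (2 * outer + 5, 2 * outer + 5)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return (r2 <= outer**2) & (r2 > inner**2)


def bar_mask(
    length: int = 40, width: int = 4, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Straight bar: one hole-free elongated component (a stripe)."""
    if shape is None:
        shape = (width + 10, length + 10)
    mask = np.zeros(shape, dtype=bool)
    r0 = (shape[0] - width) // 2
    c0 = (shape[1] - length) // 2
    mask[r0 : r0 + width, c0 : c0 + length] = True
    return mask
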