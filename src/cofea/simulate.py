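"""Synthetic peak-by-cell datasets with planted ground truth.

Five archetypes:

* ``S1`` — discrete cell types, one fixed open probability for all
  type-specific peaks (uniform accessibility).
* ``S2`` / ``S3`` — per-peak open probabilities drawn from a range
  (dynamic accessibility; S3 uses a wider, harder range).
* ``S4`` — three common types plus one rare type (<= 5% of cells).
* ``S5`` — a three-branch differentiation tree; branch-specific peaks ramp
  from the off-type to the on-type probability along pseudotime.

Each cell opens each peak independently (Bernoulli), and open sites receive
count 1 + Poisson(depth_lambda), keeping counts sparse and close-to-binary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .types import CountMatrix, Peak, ValidationError

ARCHETYPES = ("S1", "S2", "S3", "S4", "S5")
_ALIASES = {
    "S1_uniform": "S1",
    "S2_dynamic": "S2",
    "S3_dynamic_hard": "S3",
    "S4_rare": "S4",
    "S5_trajectory": "S5",
}


@dataclass
class SimulationSpec:
    archetype: str = "S1"
    n_cells_per_type: list[int] = field(default_factory=lambda: [250, 250, 250, 250])
    n_specific_peaks_per_type: int = 200
    n_background_peaks: int = 1000
    p_open_specific: float | tuple[float, float] = 0.6
    p_open_offtype: float = 0.05
    p_open_background: float = 0.2
    depth_lambda: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetype = _ALIASES.get(self.archetype, self.archetype)
        if self.archetype not in ARCHETYPES:
            raise ValidationError(
                f"unknown archetype {self.archetype!r}; use one of {ARCHETYPES}"
            )
        spec_lo = (
            self.p_open_specific[0]
            if isinstance(self.p_open_specific, (tuple, list))
            else self.p_open_specific
        )
        probs = [spec_lo, self.p_open_offtype, self.p_open_background]
        if isinstance(self.p_open_specific, (tuple, list)):
            lo, hi = self.p_open_specific
            if lo > hi:
                raise ValidationError(f"inverted probability range ({lo}, {hi})")
            probs.append(hi)
        for pr in probs:
            if not 0 <= pr <= 1:
                raise ValidationError(f"probability {pr} outside [0, 1]")
        if spec_lo <= self.p_open_offtype:
            raise ValidationError(
                "p_open_specific (range minimum) must exceed p_open_offtype"
            )
        if self.archetype == "S4":
            total = sum(self.n_cells_per_type)
            if min(self.n_cells_per_type) / total > 0.05:
                raise ValidationError(
                    "S4 requires a rare type with <= 5% of all cells"
                )

    @classmethod
    def default(cls, archetype: str, seed: int = 0, **overrides) -> "SimulationSpec":
        archetype = _ALIASES.get(archetype, archetype)
        base: dict = {"archetype": archetype, "seed": seed}
        if archetype == "S2":
            base["p_open_specific"] = (0.4, 0.8)
        elif archetype == "S3":
            base["p_open_specific"] = (0.2, 0.9)
        elif archetype == "S4":
            base["n_cells_per_type"] = [300, 300, 300, 30]
        elif archetype == "S5":
            base["n_cells_per_type"] = [340, 330, 330]  # root, branch B, branch C
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        d = asdict(self)
        if isinstance(d["p_open_specific"], tuple):
            d["p_open_specific"] = list(d["p_open_specific"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationSpec":
        d = json.loads(text)
        if isinstance(d.get("p_open_specific"), list):
            d["p_open_specific"] = tuple(d["p_open_specific"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    truth_specific: dict[int, str]  # peak index -> owning cell type / branch
    truth_background: set[int]
    spec: SimulationSpec

    def __post_init__(self) -> None:
        all_idx = set(self.truth_specific) | self.truth_background
        if all_idx != set(range(self.counts.p)) or (
            set(self.truth_specific) & self.truth_background
        ):
            raise ValidationError("truth_specific/background do not partition peaks")

    @property
    def specific_set(self) -> set[int]:
        return set(self.truth_specific)

    def specific_of(self, owner: str) -> set[int]:
        return {i for i, t in self.truth_specific.items() if t == owner}


def _type_names(n_types: int) -> list[str]:
    return [chr(ord("A") + t) for t in range(n_types)]


def _draw_counts(
    open_prob: np.ndarray, depth_lambda: float, rng: np.random.Generator
) -> np.ndarray:
    opened = rng.random(open_prob.shape) < open_prob
    counts = np.zeros(open_prob.shape, dtype=np.int64)
    n_open = int(opened.sum())
    if n_open:
        counts[opened] = 1 + rng.poisson(depth_lambda, size=n_open)
    return counts


def simulate(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a dataset with planted type-specific peaks; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.archetype == "S5":
        return _simulate_trajectory(spec, rng)
    return _simulate_discrete(spec, rng)


def _open_prob_specific(spec: SimulationSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.p_open_specific, (tuple, list)):
        lo, hi = spec.p_open_specific
        return rng.uniform(lo, hi, size=size)
    return np.full(size, float(spec.p_open_specific))


def _peak_intervals(p: int) -> list[Peak]:
    return [Peak("chrS", i * 1000, i * 1000 + 500) for i in range(p)]


def _simulate_discrete(spec: SimulationSpec, rng: np.random.Generator) -> SimulatedDataset:
    n_types = len(spec.n_cells_per_type)
    types = _type_names(n_types)
    k_spec = spec.n_specific_peaks_per_type
    p = n_types * k_spec + spec.n_background_peaks
    n = sum(spec.n_cells_per_type)

    # per-peak on-type open probability (fixed for S1/S4, drawn for S2/S3)
    on_prob = _open_prob_specific(spec, n_types * k_spec, rng)
    prob = np.full((p, n), np.nan)
    col = 0
    for t, n_t in enumerate(spec.n_cells_per_type):
        block = np.full((p, n_t), spec.p_open_background)
        for t2 in range(n_types):
            rows = slice(t2 * k_spec, (t2 + 1) * k_spec)
            if t2 == t:
                block[rows] = on_prob[rows][:, np.newaxis]
            else:
                block[rows] = spec.p_open_offtype
        prob[:, col : col + n_t] = block
        col += n_t

    counts = _draw_counts(prob, spec.depth_lambda, rng)
    barcodes = [f"cell_{i:05d}" for i in range(n)]
    labels: dict[str, str] = {}
    col = 0
    for t, n_t in enumerate(spec.n_cells_per_type):
        for i in range(col, col + n_t):
            labels[barcodes[i]] = types[t]
        col += n_t
    truth_specific = {
        t * k_spec + j: types[t] for t in range(n_types) for j in range(k_spec)
    }
    truth_background = set(range(n_types * k_spec, p))
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        peaks=_peak_intervals(p),
        barcodes=barcodes,
        labels=labels,
    )
    return SimulatedDataset(cm, truth_specific, truth_background, spec)


def _simulate_trajectory(spec: SimulationSpec, rng: np.random.Generator) -> SimulatedDataset:
    """Three-branch tree: root on pseudotime [0, 0.5], two children on [0.5, 1]."""
    if len(spec.n_cells_per_type) != 3:
        raise ValidationError("S5 requires 3 branch sizes (root, child B, child C)")
    branches = ["root", "B", "C"]
    k_spec = spec.n_specific_peaks_per_type
    p = 3 * k_spec + spec.n_background_peaks
    n = sum(spec.n_cells_per_type)

    branch_of = np.repeat(np.arange(3), spec.n_cells_per_type)
    local_t = rng.random(n)  # position along the owning branch, in [0, 1)
    on_hi = _open_prob_specific(spec, 3 * k_spec, rng)

    prob = np.full((p, n), spec.p_open_background)
    off = spec.p_open_offtype
    for b in range(3):
        rows = slice(b * k_spec, (b + 1) * k_spec)
        on_cells = branch_of == b
        ramp = off + (on_hi[rows][:, np.newaxis] - off) * local_t[on_cells][np.newaxis, :]
        prob[rows, :] = off
        sub = prob[rows]
        sub[:, on_cells] = ramp
        prob[rows] = sub

    counts = _draw_counts(prob, spec.depth_lambda, rng)
    barcodes = [f"cell_{i:05d}" for i in range(n)]
    labels = {bc: branches[branch_of[i]] for i, bc in enumerate(barcodes)}
    truth_specific = {
        b * k_spec + j: branches[b] for b in range(3) for j in range(k_spec)
    }
    truth_background = set(range(3 * k_spec, p))
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        peaks=_peak_intervals(p),
        barcodes=barcodes,
        labels=labels,
    )
    return SimulatedDataset(cm, truth_specific, truth_background, spec)


def inject_dropout(cm: CountMatrix, rate: float, seed: int = 0) -> CountMatrix:
    """Zero each nonzero entry independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValidationError(f"dropout rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    coo = cm.values.tocoo()
    keep = rng.random(coo.nnz) >= rate
    values = sp.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=coo.shape
    )
    return CountMatrix(
        values=values,
        peaks=list(cm.peaks),
        barcodes=list(cm.barcodes),
        labels=cm.labels,
    )
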