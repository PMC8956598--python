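"""Synthetic study cohort: donors, cell lines, matched pairs, and plate layouts.

The cohort emulates a population-scale fibroblast screen: 91 skin-biopsy donors
(45 healthy controls, 32 sporadic PD, 8 GBA PD, 6 LRRK2 PD), five of whom donated
a second biopsy years later, for 96 cell lines in total.  Each line carries a
vector of morphology parameters (per-channel staining intensity, nucleus/cell
geometry, texture grain, radial skew) composed of a population baseline plus
donor-level, line-level (per biopsy) and disease-level effects.  PD donors are
demographically matched to healthy controls in pairs (age, sex), which later
anchor both the checkerboard plate layouts and the disease cross-validation
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CHANNELS = ("DAPI", "ER", "RNA", "AGP", "MITO")

#: morphology parameter names, their population baselines and between-subject SDs.
#: Areas are in pixels^2 at the default rendering scale; intensities in 16-bit
#: camera counts; grain radii in pixels; radial skew is unitless in [-1, 1].
PARAM_TABLE = [
    # name, baseline, sd, lo, hi
    ("intensity_DAPI", 9000.0, 1200.0, 500.0, 40000.0),
    ("intensity_ER", 6000.0, 900.0, 400.0, 40000.0),
    ("intensity_RNA", 6500.0, 950.0, 400.0, 40000.0),
    ("intensity_AGP", 5500.0, 850.0, 400.0, 40000.0),
    ("intensity_MITO", 7000.0, 1000.0, 400.0, 40000.0),
    ("nucleus_area_mean", 150.0, 25.0, 40.0, 4000.0),
    ("nucleus_area_sd", 30.0, 6.0, 2.0, 400.0),
    ("cell_area_mean", 700.0, 110.0, 150.0, 20000.0),
    ("cell_area_sd", 120.0, 25.0, 10.0, 2000.0),
    ("eccentricity", 0.55, 0.08, 0.05, 0.92),
    ("grain_radius_DAPI", 2.2, 0.5, 0.8, 6.0),
    ("grain_radius_ER", 2.2, 0.5, 0.8, 6.0),
    ("grain_radius_RNA", 2.2, 0.5, 0.8, 6.0),
    ("grain_radius_AGP", 2.2, 0.5, 0.8, 6.0),
    ("grain_radius_MITO", 2.2, 0.5, 0.8, 6.0),
    ("radial_skew_DAPI", 0.0, 0.35, -0.9, 0.9),
    ("radial_skew_ER", 0.0, 0.35, -0.9, 0.9),
    ("radial_skew_RNA", 0.0, 0.35, -0.9, 0.9),
    ("radial_skew_AGP", 0.0, 0.35, -0.9, 0.9),
    ("radial_skew_MITO", 0.0, 0.35, -0.9, 0.9),
]
PARAM_NAMES = tuple(t[0] for t in PARAM_TABLE)
PARAM_BASELINE = np.array([t[1] for t in PARAM_TABLE])
PARAM_SD = np.array([t[2] for t in PARAM_TABLE])
PARAM_LO = np.array([t[3] for t in PARAM_TABLE])
PARAM_HI = np.array([t[4] for t in PARAM_TABLE])

GROUPS = ("healthy", "sporadic", "GBA", "LRRK2")


class CohortError(ValueError):
    """Invalid cohort specification."""


class PairingError(ValueError):
    """PD/control demographic pairing could not be completed."""

    def __init__(self, unpaired: list[int]):
        self.unpaired = list(unpaired)
        super().__init__(
            f"{len(self.unpaired)} PD line(s) could not be paired with a healthy "
            f"control: {self.unpaired}"
        )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic donor cohort.

    Effect scales are in units of the per-parameter population SD: a donor
    (line) effect adds N(0, scale*SD) per parameter per donor (biopsy); the
    disease effect shifts a seeded subset of parameters of every PD line by
    ``disease_effect_scale * SD`` in a fixed seeded direction.
    """

    n_donors: int = 91
    group_counts: dict = field(
        default_factory=lambda: {"healthy": 45, "sporadic": 32, "GBA": 8, "LRRK2": 6}
    )
    n_repeat_biopsy_donors: int = 5
    age_mean: float = 66.0
    age_sd: float = 8.0
    sex_ratio: float = 0.5
    pair_age_tolerance: float = 5.0
    disease_effect_scale: float = 0.0
    donor_effect_scale: float = 1.0
    line_effect_scale: float = 0.5
    disease_effect_fraction: float = 0.3
    n_discordant_repeat_donors: int = 1
    max_unpaired_pd: int = 1
    seed: int = 0

    def validate(self) -> None:
        if set(self.group_counts) != set(GROUPS):
            raise CohortError(f"group_counts must have keys {GROUPS}")
        if sum(self.group_counts.values()) != self.n_donors:
            raise CohortError(
                f"group counts sum to {sum(self.group_counts.values())}, "
                f"expected n_donors={self.n_donors}"
            )
        if self.n_repeat_biopsy_donors > self.n_donors:
            raise CohortError("n_repeat_biopsy_donors exceeds n_donors")
        for name in ("disease_effect_scale", "donor_effect_scale", "line_effect_scale"):
            if getattr(self, name) < 0:
                raise CohortError(f"{name} must be non-negative")
        if not 0 <= self.disease_effect_fraction <= 1:
            raise CohortError("disease_effect_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class LineProfile:
    """One cell line (one biopsy of one donor) and its morphology parameters."""

    line_id: int
    donor_id: int
    biopsy_index: int
    disease_state: str  # "healthy" | "PD"
    mutation_group: str  # "none" | "sporadic" | "GBA" | "LRRK2"
    age: float
    sex: str  # "M" | "F"
    pair_id: int | None
    morphology_params: dict

    def param_vector(self) -> np.ndarray:
        return np.array([self.morphology_params[n] for n in PARAM_NAMES])


def _clip_params(vec: np.ndarray) -> np.ndarray:
    return np.clip(vec, PARAM_LO, PARAM_HI)


def build_cohort(spec: CohortSpec) -> tuple[list[LineProfile], pd.DataFrame]:
    """Build the synthetic cohort.

    Returns the list of :class:`LineProfile` (default 96: one line per donor
    plus one second-biopsy line for each repeat donor) and the matched-pair
    table with one row per PD/control pair (columns ``pair_id, healthy_line_id,
    pd_line_id, mutation_group, age_healthy, age_pd, sex``).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root)

    gc = spec.group_counts
    n_healthy = gc["healthy"]
    # donor ids: healthy first, then sporadic, GBA, LRRK2
    groups: list[str] = (
        ["healthy"] * n_healthy
        + ["sporadic"] * gc["sporadic"]
        + ["GBA"] * gc["GBA"]
        + ["LRRK2"] * gc["LRRK2"]
    )

    n_params = len(PARAM_NAMES)
    # disease signature: fixed seeded subset of parameters and directions
    sig_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    k = max(1, round(spec.disease_effect_fraction * n_params))
    disease_idx = sig_rng.choice(n_params, size=k, replace=False)
    disease_dir = sig_rng.choice([-1.0, 1.0], size=k)
    disease_shift = np.zeros(n_params)
    disease_shift[disease_idx] = disease_dir * PARAM_SD[disease_idx]

    # ---- demographics: PD donors drawn, healthy controls matched to a PD partner
    pd_donor_ids = [i for i, g in enumerate(groups, start=1) if g != "healthy"]
    healthy_donor_ids = [i for i, g in enumerate(groups, start=1) if g == "healthy"]
    n_pairs = min(len(healthy_donor_ids), len(pd_donor_ids))
    # pair GBA and LRRK2 donors with priority (all familial PD is matched),
    # then sporadic donors up to the number of available controls
    pd_priority = [i for i in pd_donor_ids if groups[i - 1] in ("GBA", "LRRK2")]
    pd_rest = [i for i in pd_donor_ids if groups[i - 1] == "sporadic"]
    paired_pd = (pd_priority + pd_rest)[:n_pairs]
    unpaired_pd = [i for i in pd_donor_ids if i not in set(paired_pd)]
    if len(unpaired_pd) > spec.max_unpaired_pd:
        raise PairingError(unpaired_pd)

    age = np.zeros(len(groups) + 1)  # 1-based
    sex = np.empty(len(groups) + 1, dtype=object)
    for d in pd_donor_ids:
        age[d] = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 40.0, 90.0))
        sex[d] = "M" if rng.random() < spec.sex_ratio else "F"
    pair_rows = []
    for pid, (h, p) in enumerate(zip(healthy_donor_ids, paired_pd), start=1):
        jitter = rng.uniform(-spec.pair_age_tolerance * 0.6, spec.pair_age_tolerance * 0.6)
        age[h] = float(np.clip(age[p] + jitter, 40.0, 90.0))
        sex[h] = sex[p]
        pair_rows.append((pid, h, p, groups[p - 1], age[h], age[p], sex[p]))
    for d in unpaired_pd:
        pass  # demographics already drawn; no partner
    for d in healthy_donor_ids[len(paired_pd):]:  # pragma: no cover - only if PD < healthy
        age[d] = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 40.0, 90.0))
        sex[d] = "M" if rng.random() < spec.sex_ratio else "F"

    # ---- morphology effects
    donor_z = rng.standard_normal((len(groups) + 1, n_params))
    repeat_donors = sorted(
        rng.choice(np.arange(1, len(groups) + 1), size=spec.n_repeat_biopsy_donors, replace=False).tolist()
    )
    discordant = set(repeat_donors[: spec.n_discordant_repeat_donors])

    pair_of_donor = {h: pid for pid, h, p, *_ in pair_rows}
    pair_of_donor.update({p: pid for pid, h, p, *_ in pair_rows})

    def make_line(line_id: int, donor: int, biopsy: int) -> LineProfile:
        g = groups[donor - 1]
        state = "healthy" if g == "healthy" else "PD"
        dz = donor_z[donor].copy()
        if biopsy == 2 and donor in discordant:
            # a discordant second biopsy (e.g. different body site) redraws
            # half of the donor-level components
            mask = rng.random(n_params) < 0.5
            dz[mask] = rng.standard_normal(mask.sum())
        lz = rng.standard_normal(n_params)
        vec = (
            PARAM_BASELINE
            + spec.donor_effect_scale * PARAM_SD * dz
            + spec.line_effect_scale * PARAM_SD * lz
        )
        if state == "PD":
            vec = vec + spec.disease_effect_scale * disease_shift
        vec = _clip_params(vec)
        return LineProfile(
            line_id=line_id,
            donor_id=donor,
            biopsy_index=biopsy,
            disease_state=state,
            mutation_group="none" if g == "healthy" else g,
            age=round(age[donor], 1),
            sex=sex[donor],
            pair_id=pair_of_donor.get(donor),
            morphology_params=dict(zip(PARAM_NAMES, vec)),
        )

    lines = [make_line(i, i, 1) for i in range(1, len(groups) + 1)]
    next_id = len(groups) + 1
    for donor in repeat_donors:
        lines.append(make_line(next_id, donor, 2))
        next_id += 1

    pairs = pd.DataFrame(
        pair_rows,
        columns=["pair_id", "healthy_line_id", "pd_line_id", "mutation_group",
                 "age_healthy", "age_pd", "sex"],
    )
    return lines, pairs


def cohort_table(lines: list[LineProfile]) -> pd.DataFrame:
    """Flatten LineProfiles to a DataFrame (one row per line)."""
    rows = []
    for ln in lines:
        row = {
            "line_id": ln.line_id,
            "donor_id": ln.donor_id,
            "biopsy_index": ln.biopsy_index,
            "disease_state": ln.disease_state,
            "mutation_group": ln.mutation_group,
            "age": ln.age,
            "sex": ln.sex,
            "pair_id": -1 if ln.pair_id is None else ln.pair_id,
        }
        row.update(ln.morphology_params)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate layouts

N_ROWS, N_COLS = 8, 12
QUAD_ROWS, QUAD_COLS = 4, 6


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A01'..'H12'."""
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def well_coords(name: str) -> tuple[int, int]:
    return ord(name[0]) - ord("A"), int(name[1:]) - 1


@dataclass(frozen=True)
class PlateLayout:
    """An 8x12 assignment of the 96 line ids to wells."""

    layout_id: int
    grid: np.ndarray  # (8, 12) int

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.shape != (N_ROWS, N_COLS):
            raise ValueError("layout grid must be 8x12")
        object.__setattr__(self, "grid", g)

    def line_at(self, well: str) -> int:
        r, c = well_coords(well)
        return int(self.grid[r, c])

    def well_of(self, line_id: int) -> str:
        r, c = np.argwhere(self.grid == line_id)[0]
        return well_name(int(r), int(c))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"layout": self.layout_id, "well": well_name(r, c),
             "line_id": int(self.grid[r, c])}
            for r in range(N_ROWS) for c in range(N_COLS)
        ]
        return pd.DataFrame(rows)


def quadrant_translate(grid: np.ndarray) -> np.ndarray:
    """Exchange the four 4x6 quadrants diagonally across the plate center.

    Top-left <-> bottom-right and top-right <-> bottom-left, preserving the
    within-quadrant arrangement; the map is an involution and moves every well
    by a Manhattan distance of 10, so edge wells end up near the center.
    """
    return np.roll(grid, shift=(QUAD_ROWS, QUAD_COLS), axis=(0, 1))


def build_layouts(lines: list[LineProfile], seed: int = 0) -> tuple[PlateLayout, PlateLayout]:
    """Construct the two plate layouts from randomly permuted matched pairs.

    Layout 1 fills the 48 horizontal well-pairs with the shuffled PD/control
    pairs, alternating which member sits on the even column so control and PD
    wells alternate in a checkerboard-like pattern; lines without a partner
    (the unmatched PD line and the second-biopsy lines) fill the remaining
    well-pairs.  Layout 2 is the diagonal quadrant translation of layout 1.
    """
    if len(lines) != N_ROWS * N_COLS:
        raise ValueError(f"build_layouts needs exactly 96 lines, got {len(lines)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    by_id = {ln.line_id: ln for ln in lines}

    pair_map: dict[int, list[int]] = {}
    for ln in lines:
        if ln.pair_id is not None and ln.biopsy_index == 1:
            pair_map.setdefault(ln.pair_id, []).append(ln.line_id)
    duos = [sorted(v, key=lambda i: by_id[i].disease_state) for v in pair_map.values()
            if len(v) == 2]  # [healthy, PD] (alphabetical: PD < healthy? enforce below)
    for d in duos:
        if by_id[d[0]].disease_state != "healthy":
            d.reverse()
    leftovers = sorted(
        ln.line_id for ln in lines
        if ln.biopsy_index == 2 or ln.pair_id is None
    )
    rng.shuffle(duos)
    leftover_perm = list(leftovers)
    rng.shuffle(leftover_perm)
    # group leftovers into pseudo-duos (healthy-ish first where possible)
    extra = [leftover_perm[i:i + 2] for i in range(0, len(leftover_perm), 2)]
    slots = duos + extra

    grid = np.zeros((N_ROWS, N_COLS), dtype=int)
    s = 0
    for r in range(N_ROWS):
        for cpair in range(N_COLS // 2):
            duo = slots[s]
            s += 1
            if len(duo) == 1:  # pragma: no cover - only for odd leftover counts
                grid[r, 2 * cpair] = duo[0]
                continue
            healthy, pdl = duo[0], duo[1]
            # healthy on wells with even (row+col) parity -> checkerboard
            if r % 2 == 0:
                grid[r, 2 * cpair], grid[r, 2 * cpair + 1] = healthy, pdl
            else:
                grid[r, 2 * cpair], grid[r, 2 * cpair + 1] = pdl, healthy
    layout1 = PlateLayout(1, grid)
    layout2 = PlateLayout(2, quadrant_translate(grid))
    return layout1, layout2
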