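"""Synthetic multi-operator landmark studies with known ground truth.

The generator emulates the two designs the error analysis needs:

* a *replica* design — every operator digitizes every individual (default:
  20 individuals x 3 operators = 60 observations, a single sex), used for
  absolute-error and reliability analyses; and
* a *study* design — each individual digitized by exactly one operator
  (default: 906 individuals with the unbalanced sex-by-operator cells
  F/M = 102/61, 106/163, 252/222), used for the operator-bias exploration.

Each record is built as: individual true configuration (template + isotropic
Gaussian individual shape deviation, rescaled to the individual's centroid
size) + a fixed per-operator bias field + independent digitizing noise whose
per-coordinate SD is larger on bone than on soft-tissue landmarks (default
ratio 1.65).  Sex effects (a size shift and a fixed shape displacement field)
are applied to the true configurations before operator bias and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import DEFAULT_PANEL, LandmarkConfiguration, LandmarkDataset, LandmarkPanel

#: plausible adult-face landmark positions (mm) before centring/scaling;
#: bilateral points listed for the right side and mirrored across X = 0.
_TEMPLATE_MM: dict[str, tuple[float, float, float]] = {
    "Glabella": (0.0, 95.0, 35.0),
    "Soft nasion": (0.0, 93.0, 25.0),
    "Hard nasion": (0.0, 88.0, 24.0),
    "Pronasale": (0.0, 110.0, -5.0),
    "Subnasale": (0.0, 98.0, -15.0),
    "Anterior nasal spine": (0.0, 92.0, -14.0),
    "Sella": (0.0, 15.0, 15.0),
    "Alare right": (17.0, 90.0, -8.0),
    "Orbitale right": (32.0, 75.0, 5.0),
    "Porion right": (60.0, 5.0, 10.0),
    "Zygion right": (65.0, 55.0, -5.0),
}


def _template_coords(panel: LandmarkPanel) -> np.ndarray:
    coords = np.empty((panel.size, 3))
    for i, (name, side) in enumerate(zip(panel.names, panel.side)):
        if side == "left":
            x, y, z = _TEMPLATE_MM[name.replace(" left", " right")]
            coords[i] = (-x, y, z)
        else:
            coords[i] = _TEMPLATE_MM[name]
    return coords


def _scale_to_cs(coords: np.ndarray, cs: float) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    return centred * (cs / np.sqrt((centred**2).sum()))


def make_template(
    panel: LandmarkPanel = DEFAULT_PANEL, mean_size: float = 230.0
) -> LandmarkConfiguration:
    """Bilaterally symmetric mean face, centroid at origin, CS = mean_size."""
    return LandmarkConfiguration(
        individual_id="template",
        operator_id="template",
        sex="unknown",
        replicate_id="r0",
        coords=_scale_to_cs(_template_coords(panel), mean_size),
    )


def _field_from_offsets(
    panel: LandmarkPanel, offsets: Mapping[str, tuple[float, float, float]]
) -> np.ndarray:
    out = np.zeros((panel.size, 3))
    for name, v in offsets.items():
        if name in panel.names:
            out[panel.names.index(name)] = v
    return out


def default_sex_shape_field(panel: LandmarkPanel = DEFAULT_PANEL) -> np.ndarray:
    """Male-minus-female shape displacement, normalized to unit per-coordinate RMS.

    The pattern is a mild masculinization: more prominent glabella and brow,
    wider zygions, larger and wider nose.
    """
    raw = _field_from_offsets(
        panel,
        {
            "Glabella": (0.0, 1.2, 0.3),
            "Hard nasion": (0.0, 0.6, 0.0),
            "Pronasale": (0.0, 1.0, -0.3),
            "Subnasale": (0.0, 0.5, -0.3),
            "Alare left": (-0.6, 0.3, 0.0),
            "Alare right": (0.6, 0.3, 0.0),
            "Zygion left": (-1.0, 0.2, 0.0),
            "Zygion right": (1.0, 0.2, 0.0),
            "Porion left": (-0.4, 0.0, 0.0),
            "Porion right": (0.4, 0.0, 0.0),
        },
    )
    rms = np.sqrt((raw**2).mean())
    return raw / rms


def _cs_direction(template: np.ndarray, idx: tuple[int, ...]) -> np.ndarray:
    """Gradient direction of a subset's centroid size at the template."""
    u = np.zeros_like(template)
    sub = template[list(idx)]
    u[list(idx)] = sub - sub.mean(axis=0)
    return u


def _cs_neutralize(
    field: np.ndarray, template: np.ndarray, idx_sets: list[tuple[int, ...]]
) -> np.ndarray:
    """Project out the components of a bias field that change the centroid
    sizes of the given landmark subsets (to first order at the template)."""
    dirs: list[np.ndarray] = []
    for idx in idx_sets:
        u = _cs_direction(template, idx).ravel()
        for d in dirs:
            u = u - (u @ d) * d
        norm = np.linalg.norm(u)
        if norm > 1e-12:
            dirs.append(u / norm)
    f = field.ravel().copy()
    for d in dirs:
        f -= (f @ d) * d
    return f.reshape(field.shape)


#: systematic nasal-size misjudgment per operator (Delta of nose centroid
#: size, mm): OP2 slightly under-, OP3 clearly over-estimates nasal size.
NOSE_SIZE_BIAS_MM = {"OP1": 0.0, "OP2": -0.3, "OP3": 1.2}


def default_operator_bias(
    panel: LandmarkPanel = DEFAULT_PANEL,
) -> dict[str, np.ndarray]:
    """Fixed per-operator placement-bias fields (mm).

    OP1 is the reference (zero field).  OP2 and OP3 consistently displace the
    low-contrast bone landmarks (porion, zygion, orbitale, sella, glabella)
    and the nasal soft-tissue points, each in their own direction.  The
    fields are made centroid-size-neutral for the all/bone/nose subsets (to
    first order at the template), then an explicit nasal-size misjudgment
    (``NOSE_SIZE_BIAS_MM``) is added back along the nose-size gradient — so
    operator bias is almost invisible in full-face and bone size but clearly
    visible in nasal size, while remaining substantial in shape.
    """
    template = _scale_to_cs(_template_coords(panel), 230.0)
    op2 = _field_from_offsets(
        panel,
        {
            "Porion left": (2.5, 3.0, -2.0),
            "Porion right": (-2.5, 3.0, -2.0),
            "Sella": (0.0, 2.5, 2.5),
            "Orbitale left": (0.0, 1.0, 2.0),
            "Orbitale right": (0.0, 1.0, 2.0),
            "Glabella": (0.0, 1.25, 1.0),
            "Zygion left": (1.25, 0.0, 0.75),
            "Zygion right": (-1.25, 0.0, 0.75),
            "Soft nasion": (0.0, 1.15, 0.0),
            "Pronasale": (0.0, 0.0, 1.25),
            "Subnasale": (0.0, 1.05, 0.0),
            "Alare left": (0.0, 0.0, 0.9),
            "Alare right": (0.0, 0.0, 0.9),
        },
    )
    op3 = _field_from_offsets(
        panel,
        {
            "Zygion left": (-3.0, 0.75, 0.0),
            "Zygion right": (3.0, 0.75, 0.0),
            "Porion left": (-1.25, 0.0, 2.5),
            "Porion right": (1.25, 0.0, 2.5),
            "Hard nasion": (0.0, -2.0, 0.75),
            "Anterior nasal spine": (0.0, -1.25, 1.0),
            "Sella": (0.0, -1.5, -1.25),
            "Soft nasion": (0.0, -0.9, 0.0),
            "Pronasale": (0.0, 0.35, -1.15),
            "Subnasale": (0.0, -0.7, 0.55),
            "Alare left": (-0.7, 0.55, -0.8),
            "Alare right": (0.7, 0.55, -0.8),
        },
    )
    idx_sets = [
        panel.subsets[name] for name in ("all", "bone", "nose")
        if name in panel.subsets
    ]
    op2 = _cs_neutralize(op2, template, idx_sets)
    op3 = _cs_neutralize(op3, template, idx_sets)
    if "nose" in panel.subsets:
        u_nose = _cs_direction(template, panel.subsets["nose"])
        cs_nose = np.sqrt((u_nose**2).sum())
        op2 = op2 + (NOSE_SIZE_BIAS_MM["OP2"] / cs_nose) * u_nose
        op3 = op3 + (NOSE_SIZE_BIAS_MM["OP3"] / cs_nose) * u_nose
    return {"OP1": np.zeros((panel.size, 3)), "OP2": op2, "OP3": op3}


#: the study sample's unbalanced sex-by-operator cell counts (F, M per operator)
STUDY_SEX_COUNTS: dict[tuple[str, str], int] = {
    ("OP1", "F"): 102,
    ("OP1", "M"): 61,
    ("OP2", "F"): 106,
    ("OP2", "M"): 163,
    ("OP3", "F"): 252,
    ("OP3", "M"): 222,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-operator landmark study (units mm)."""

    n_individuals: int = 20
    operators: tuple[str, ...] = ("OP1", "OP2", "OP3")
    replicate_design: str = "full"  # "full" (replica) | "partition" (study)
    sex_counts: dict[tuple[str, str], int] | None = None
    mean_size: float = 230.0
    individual_shape_sd: float = 1.5
    individual_size_sd: float = 6.0
    sex_size_shift: float = 14.0
    sex_shape_magnitude: float = 0.5
    sex_shape_field: np.ndarray | None = None  # unit-RMS displacement, p x 3
    operator_bias: dict[str, np.ndarray] | None = None  # mm fields, p x 3
    noise_sd_bone: float = 0.924  # 1.65 x noise_sd_soft
    noise_sd_soft: float = 0.56
    seed: int = 42
    panel: LandmarkPanel = field(default=DEFAULT_PANEL)

    def __post_init__(self) -> None:
        for name in ("individual_shape_sd", "individual_size_sd",
                     "noise_sd_bone", "noise_sd_soft"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicate_design not in ("full", "partition"):
            raise ValueError("replicate_design must be 'full' or 'partition'")
        if self.replicate_design == "partition":
            if self.sex_counts is None:
                raise ValueError("partition designs require sex_counts")
            if sum(self.sex_counts.values()) != self.n_individuals:
                raise ValueError(
                    f"sex_counts sum to {sum(self.sex_counts.values())}, "
                    f"not n_individuals={self.n_individuals}"
                )
            for op, _sex in self.sex_counts:
                if op not in self.operators:
                    raise ValueError(f"sex_counts references unknown operator {op!r}")

    def resolved_bias(self) -> dict[str, np.ndarray]:
        bias = (
            default_operator_bias(self.panel)
            if self.operator_bias is None
            else dict(self.operator_bias)
        )
        missing = [op for op in self.operators if op not in bias]
        if missing:
            raise ValueError(f"no bias field for operators {missing}")
        return {op: np.asarray(bias[op], float) for op in self.operators}

    def resolved_sex_field(self) -> np.ndarray:
        f = (
            default_sex_shape_field(self.panel)
            if self.sex_shape_field is None
            else np.asarray(self.sex_shape_field, float)
        )
        if f.shape != (self.panel.size, 3):
            raise ValueError("sex_shape_field must be p x 3")
        return f

    def noise_sd_per_landmark(self) -> np.ndarray:
        return np.array(
            [
                self.noise_sd_bone if t == "bone" else self.noise_sd_soft
                for t in self.panel.tissue
            ]
        )


def replica_spec(**overrides) -> SyntheticSpec:
    """The replica-design study conditions: 20 individuals x 3 operators."""
    return SyntheticSpec(**{"replicate_design": "full", **overrides})


def study_spec(**overrides) -> SyntheticSpec:
    """The study-design conditions: 906 individuals, printed sex/operator cells.

    The study population is more heterogeneous than the deliberately
    homogeneous single-sex replica sample, so its default individual shape
    variance is larger (the operator-bias fields and noise are identical —
    the same three operators digitize both samples).
    """
    defaults = {
        "replicate_design": "partition",
        "sex_counts": dict(STUDY_SEX_COUNTS),
        "n_individuals": sum(STUDY_SEX_COUNTS.values()),
        "individual_shape_sd": 2.4,
        "sex_shape_magnitude": 0.75,
    }
    return SyntheticSpec(**{**defaults, **overrides})


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset, for parameter-recovery tests."""

    spec: SyntheticSpec
    seed: int
    true_configs: dict[str, np.ndarray]  # individual_id -> p x 3 (pre-noise, pre-bias)
    operator_bias: dict[str, np.ndarray]
    noise_ss_shape: float  # realized noise SS in unit-CS shape units
    design_fractions: dict[str, float]  # expected share of shape variance


def _shape_units(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def _design_fractions(
    true_configs: dict[str, np.ndarray],
    bias: dict[str, np.ndarray],
    noise_ss_shape: float,
    k_per_individual: Mapping[str, int] | int,
    n_records_per_operator: Mapping[str, int],
    mean_size: float,
    sex_of: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Brute-force shape-variance shares of individual / sex / operator / noise.

    Computed in unit-centroid-size shape units: each component's contribution
    to the total sum of squares a shape analysis would see, ignoring the
    (second-order) effect of the Procrustes rotations.
    """
    units = {i: _shape_units(c) for i, c in true_configs.items()}
    ids = sorted(units)
    u = np.stack([units[i] for i in ids])
    if isinstance(k_per_individual, int):
        k = {i: k_per_individual for i in ids}
    else:
        k = dict(k_per_individual)
    w = np.array([k[i] for i in ids], dtype=float)
    grand = (u * w[:, None, None]).sum(axis=0) / w.sum()
    ss_between_ind = float((w[:, None, None] * (u - grand) ** 2).sum())

    ss_sex = 0.0
    if sex_of is not None and len(set(sex_of.values())) > 1:
        for s in sorted(set(sex_of.values())):
            sel = np.array([sex_of[i] == s for i in ids])
            ws = w[sel].sum()
            mean_s = (u[sel] * w[sel, None, None]).sum(axis=0) / ws
            ss_sex += float(ws * ((mean_s - grand) ** 2).sum())
    ss_ind = ss_between_ind - ss_sex

    b = {op: np.asarray(f, float) / mean_size for op, f in bias.items()}
    counts = dict(n_records_per_operator)
    total_n = sum(counts.values())
    bbar = sum(counts[op] * b[op] for op in counts) / total_n
    ss_op = float(sum(counts[op] * ((b[op] - bbar) ** 2).sum() for op in counts))

    total = ss_ind + ss_sex + ss_op + noise_ss_shape
    return {
        "individual": ss_ind / total,
        "sex": ss_sex / total,
        "operator": ss_op / total,
        "noise": noise_ss_shape / total,
    }


def generate_replica_study(
    spec: SyntheticSpec | None = None,
) -> tuple[LandmarkDataset, SyntheticTruth]:
    """Generate a full-replica dataset: every operator digitizes everyone."""
    spec = spec or replica_spec()
    if spec.replicate_design != "full":
        raise ValueError("generate_replica_study requires replicate_design='full'")
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    template = make_template(panel, spec.mean_size).coords
    bias = spec.resolved_bias()
    noise_sd = spec.noise_sd_per_landmark()

    records = []
    true_configs: dict[str, np.ndarray] = {}
    noise_ss_shape = 0.0
    for i in range(spec.n_individuals):
        ind = f"ind{i + 1:02d}"
        dev = rng.normal(0.0, spec.individual_shape_sd, size=template.shape)
        cs = rng.normal(spec.mean_size, spec.individual_size_sd)
        true = _scale_to_cs(template + dev, cs)
        true_configs[ind] = true
        for op in spec.operators:
            noise = rng.normal(0.0, 1.0, size=template.shape) * noise_sd[:, None]
            noise_ss_shape += float((noise**2).sum()) / cs**2
            records.append(
                LandmarkConfiguration(
                    individual_id=ind,
                    operator_id=op,
                    sex="F",
                    replicate_id=op,
                    coords=true + bias[op] + noise,
                )
            )
    dataset = LandmarkDataset(panel=panel, records=tuple(records))
    fractions = _design_fractions(
        true_configs,
        bias,
        noise_ss_shape,
        k_per_individual=len(spec.operators),
        n_records_per_operator={op: spec.n_individuals for op in spec.operators},
        mean_size=spec.mean_size,
    )
    truth = SyntheticTruth(
        spec=spec,
        seed=spec.seed,
        true_configs=true_configs,
        operator_bias=bias,
        noise_ss_shape=noise_ss_shape,
        design_fractions=fractions,
    )
    return dataset, truth


def generate_study_sample(
    spec: SyntheticSpec | None = None,
) -> tuple[LandmarkDataset, SyntheticTruth]:
    """Generate a partition-design dataset: one operator per individual."""
    spec = spec or study_spec()
    if spec.replicate_design != "partition":
        raise ValueError("generate_study_sample requires replicate_design='partition'")
    assert spec.sex_counts is not None
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    template = make_template(panel, spec.mean_size).coords
    bias = spec.resolved_bias()
    sex_field = spec.resolved_sex_field() * spec.sex_shape_magnitude
    noise_sd = spec.noise_sd_per_landmark()

    cells = [
        (op, sex)
        for op in spec.operators
        for sex in ("F", "M")
        if (op, sex) in spec.sex_counts
    ]
    records = []
    true_configs: dict[str, np.ndarray] = {}
    sex_of: dict[str, str] = {}
    noise_ss_shape = 0.0
    idx = 0
    for op, sex in cells:
        for _ in range(spec.sex_counts[(op, sex)]):
            idx += 1
            ind = f"S{idx:04d}"
            mean = template + (sex_field if sex == "M" else 0.0)
            dev = rng.normal(0.0, spec.individual_shape_sd, size=template.shape)
            cs = rng.normal(
                spec.mean_size + (spec.sex_size_shift if sex == "M" else 0.0),
                spec.individual_size_sd,
            )
            true = _scale_to_cs(mean + dev, cs)
            true_configs[ind] = true
            sex_of[ind] = sex
            noise = rng.normal(0.0, 1.0, size=template.shape) * noise_sd[:, None]
            noise_ss_shape += float((noise**2).sum()) / cs**2
            records.append(
                LandmarkConfiguration(
                    individual_id=ind,
                    operator_id=op,
                    sex=sex,
                    replicate_id="r1",
                    coords=true + bias[op] + noise,
                )
            )
    dataset = LandmarkDataset(panel=panel, records=tuple(records))
    per_op = {
        op: sum(c for (o, _s), c in spec.sex_counts.items() if o == op)
        for op in spec.operators
    }
    fractions = _design_fractions(
        true_configs,
        bias,
        noise_ss_shape,
        k_per_individual=1,
        n_records_per_operator=per_op,
        mean_size=spec.mean_size,
        sex_of=sex_of,
    )
    truth = SyntheticTruth(
        spec=spec,
        seed=spec.seed,
        true_configs=true_configs,
        operator_bias=bias,
        noise_ss_shape=noise_ss_shape,
        design_fractions=fractions,
    )
    return dataset, truth
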