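"""Synthetic cohort generator with planted genetic effects on shape modes.

The generator provides everything the pipeline needs to be verified without
restricted imaging or genotype data:

* a fixed, stylised 53-point proximal-femur outline (head, neck, greater and
  lesser trochanters, shaft) used as the template mean shape;
* a smooth orthonormal deformation-mode basis constructed orthogonal to the
  similarity-transform subspace at the template (translations, rotation,
  scaling), so planted shape variance cannot be absorbed by Procrustes
  alignment;
* Hardy–Weinberg genotypes for configurable SNPs;
* cohorts in which each subject's true mode scores are
  ``offset_k + sum_s beta_{s,k} * g_s + residual`` (residual SD chosen so the
  total score SD is ~1), rendered to landmarks, perturbed by iid landmark
  noise and a random per-subject rigid transform + positive scale, and
  written in the standard file formats;
* a truth ledger recording the drawn scores, genotypes, transforms and betas
  for recovery experiments.

Identical (config, seed) inputs reproduce outputs byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .landmark_io import (
    CohortDataset,
    CovariateTable,
    GenotypeDosageTable,
    LandmarkSet,
    write_covariates,
    write_dosages,
    write_landmarks,
)
from .gpa import to_preshape
from .ssm import ShapeModel, _fix_mode_signs

__all__ = [
    "SnpSpec",
    "CovariateParams",
    "SimulationConfig",
    "TruthLedger",
    "make_template",
    "make_mode_basis",
    "hwe_genotypes",
    "simulate_cohort",
    "simulate_longitudinal",
    "true_model",
    "DEFAULT_MODE_VARIANCES",
    "DEFAULT_SNPS",
    "COVARIATE_DEFAULTS",
]

#: Relative per-mode variances of the default 10-mode spectrum: geometric
#: decay with ratio 0.7, which puts modes 1, 2 and 5 at ~60% of the total
#: shape variance while keeping eigen-gaps wide enough for the basis to be
#: identifiable from realistic cohort sizes.
DEFAULT_MODE_VARIANCES = tuple(0.7**k for k in range(10))

#: Fixed seed for the default deformation basis so that independently
#: generated cohorts (e.g. two timepoints) share the same true model.
DEFAULT_BASIS_SEED = 170053


@dataclass(frozen=True)
class SnpSpec:
    """A simulated candidate SNP with per-mode per-allele effects."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    betas: dict[int, float] = field(default_factory=dict)  # 1-based mode -> beta

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"SNP {self.snp_id}: EAF must lie in (0, 1)")


@dataclass(frozen=True)
class CovariateParams:
    """Normal means/SDs for the covariate draws of one timepoint."""

    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float
    female_fraction: float = 0.52


COVARIATE_DEFAULTS = {
    "age14": CovariateParams(13.8, 0.20, 163.5, 7.6, 54.6, 10.9),
    "age18": CovariateParams(17.8, 0.38, 171.5, 9.2, 67.1, 13.4),
}

SCORE_OFFSET_DEFAULTS = {
    "age14": {1: 2.3, 2: 0.6, 5: -1.2},
    "age18": {1: 2.4, 2: 0.2, 5: -1.5},
}

#: Default candidate-SNP panel (effect sizes on the scale of standardised
#: mode scores per effect allele).
DEFAULT_SNPS = (
    SnpSpec("rs2158915", "G", "A", 0.35, {1: -0.054, 5: -0.072}),
    SnpSpec("rs1243579", "G", "T", 0.15, {1: 0.034}),
    SnpSpec("rs10743612", "A", "G", 0.24, {1: 0.05}),
    SnpSpec("rs73197346", "C", "T", 0.14, {1: -0.054}),
    SnpSpec("rs59341143", "C", "G", 0.15, {1: 0.023}),
    SnpSpec("rs1966265", "T", "G", 0.38, {2: 0.051}),
    SnpSpec("rs6537291", "A", "C", 0.38, {2: -0.063}),
    SnpSpec("rs1885245", "G", "A", 0.40, {2: 0.044}),
)


@dataclass
class SimulationConfig:
    """Everything needed to generate one cohort deterministically."""

    n_subjects: int = 500
    seed: int = 0
    timepoint: str = "age14"
    K: int = 10
    mode_variances: tuple[float, ...] = DEFAULT_MODE_VARIANCES
    raw_scale: float = 0.01  # overall raw deformation scale (pre-shape units)
    snps: tuple[SnpSpec, ...] = DEFAULT_SNPS
    score_offsets: dict[int, float] | None = None  # defaults by timepoint
    covariates: CovariateParams | None = None  # defaults by timepoint
    landmark_noise_sd: float = 0.0003  # iid per coordinate, pre-shape units
    nuisance_rotation_deg: float = 10.0
    nuisance_scale_range: tuple[float, float] = (150.0, 300.0)
    nuisance_translation: float = 100.0
    basis_seed: int = DEFAULT_BASIS_SEED
    id_prefix: str = "id"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.mode_variances) != self.K:
            raise ValueError("mode_variances length must equal K")
        if any(v <= 0 for v in self.mode_variances):
            raise ValueError("mode variances must be positive")
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark noise SD must be non-negative")
        lo, hi = self.nuisance_scale_range
        if not 0 < lo <= hi:
            raise ValueError("nuisance scale range must be positive")
        if self.score_offsets is None:
            self.score_offsets = dict(SCORE_OFFSET_DEFAULTS.get(self.timepoint, {}))
        if self.covariates is None:
            self.covariates = COVARIATE_DEFAULTS.get(
                self.timepoint, COVARIATE_DEFAULTS["age14"]
            )

    @property
    def mode_sds(self) -> np.ndarray:
        """Raw (unstandardised) per-mode deformation SDs."""
        return self.raw_scale * np.sqrt(np.asarray(self.mode_variances))

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["covariates"] = asdict(self.covariates)
        payload["snps"] = [asdict(s) for s in self.snps]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "covariates" in payload and payload["covariates"] is not None:
            payload["covariates"] = CovariateParams(**payload["covariates"])
        if "snps" in payload:
            payload["snps"] = tuple(
                SnpSpec(**{**s, "betas": {int(k): float(v)
                                          for k, v in s.get("betas", {}).items()}})
                for s in payload["snps"]
            )
        for key in ("mode_variances", "nuisance_scale_range"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        if payload.get("score_offsets"):
            payload["score_offsets"] = {int(k): float(v)
                                        for k, v in payload["score_offsets"].items()}
        return cls(**payload)


@dataclass
class TruthLedger:
    """Ground truth for a simulated cohort."""

    true_scores: pd.DataFrame  # index id, columns mode1..modeK (standardised)
    dosages: pd.DataFrame  # index id, columns snp ids
    transforms: pd.DataFrame  # index id: theta, scale, tx, ty
    betas: pd.DataFrame  # index snp_id, columns mode1..modeK
    seed: int = 0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.true_scores.to_csv(out / "true_scores.tsv", sep="\t")
        self.dosages.to_csv(out / "true_dosages.tsv", sep="\t")
        self.transforms.to_csv(out / "true_transforms.tsv", sep="\t")
        self.betas.to_csv(out / "true_betas.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Template and basis
# ---------------------------------------------------------------------------

# Control polygon for the stylised proximal-femur outline: lateral shaft up
# over the greater trochanter, through the neck saddle, around the femoral
# head, down past the lesser trochanter along the medial shaft.  The open
# polyline is resampled to 53 points by arc length.
_TEMPLATE_CONTROL = np.array([
    (-12.0, 0.0), (-12.0, 30.0), (-14.0, 48.0), (-20.0, 62.0), (-24.0, 78.0),
    (-18.0, 92.0), (-10.0, 86.0), (-2.0, 78.0), (6.0, 84.0), (10.0, 92.0),
    (13.7, 108.3), (21.2, 111.8), (29.5, 111.0), (36.3, 106.3), (39.8, 98.8),
    (39.0, 90.5), (34.3, 83.7), (26.8, 80.2), (22.0, 70.0), (24.0, 58.0),
    (28.0, 52.0), (26.0, 46.0), (18.0, 30.0), (16.0, 12.0), (16.0, 0.0),
])

TEMPLATE_N_POINTS = 53


def make_template(n_points: int = TEMPLATE_N_POINTS) -> LandmarkSet:
    """The fixed synthetic mean outline, resampled to ``n_points`` by arc
    length along the control polygon.  Deterministic across runs."""
    ctrl = _TEMPLATE_CONTROL
    seg = np.sqrt(((np.diff(ctrl, axis=0)) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, cum[-1], n_points)
    x = np.interp(t, cum, ctrl[:, 0])
    y = np.interp(t, cum, ctrl[:, 1])
    return LandmarkSet("template", np.column_stack([x, y]))


def _similarity_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 4-dim similarity subspace at a centred,
    unit-size configuration: x/y translation, in-plane rotation, scaling."""
    n = mean.shape[0]
    tx = np.zeros((n, 2)); tx[:, 0] = 1.0
    ty = np.zeros((n, 2)); ty[:, 1] = 1.0
    rot = np.column_stack([-mean[:, 1], mean[:, 0]])  # 90-degree rotation field
    scl = mean.copy()
    basis = np.stack([b.ravel() for b in (tx, ty, rot, scl)])
    return basis / np.linalg.norm(basis, axis=1, keepdims=True)


def make_mode_basis(template: LandmarkSet, K: int = 10,
                    seed: int = DEFAULT_BASIS_SEED) -> np.ndarray:
    """Smooth random orthonormal deformation modes for the template.

    Each mode is a low-order trigonometric series along normalised arc
    length, Gram–Schmidt-orthogonalised against the similarity-transform
    subspace at the template pre-shape and against earlier modes.  Returns a
    (K, 2 * n_points) row-orthonormal array with the standard sign
    convention applied.
    """
    n = template.n_points
    if K > 2 * n - 4:
        raise ValueError(f"K={K} exceeds the {2 * n - 4} available dimensions")
    mean = to_preshape(template).points
    forbidden = list(_similarity_basis(mean))
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n)
    modes = []
    for _ in range(K):
        for _attempt in range(50):
            field_xy = np.zeros((n, 2))
            for h in range(1, 5):
                amp = 1.0 / h
                a = rng.normal(0.0, amp, size=4)
                field_xy[:, 0] += a[0] * np.cos(np.pi * h * t) + a[1] * np.sin(np.pi * h * t)
                field_xy[:, 1] += a[2] * np.cos(np.pi * h * t) + a[3] * np.sin(np.pi * h * t)
            v = field_xy.ravel()
            for b in forbidden:
                v = v - (v @ b) * b
            # repeat for numerical orthogonality
            for b in forbidden:
                v = v - (v @ b) * b
            norm = np.linalg.norm(v)
            if norm > 1e-6:
                v /= norm
                modes.append(v)
                forbidden.append(v)
                break
        else:  # pragma: no cover - vanishing probability
            raise RuntimeError("could not draw a linearly independent mode")
    return _fix_mode_signs(np.stack(modes))


def true_model(config: SimulationConfig, training_n: int | None = None) -> ShapeModel:
    """The generative reference model implied by a simulation config.

    Mean and modes are expressed in the canonical orientation used by the
    alignment stage, so models built from simulated cohorts are directly
    comparable (same frame, same sign convention).
    """
    from .gpa import canonical_rotation_angle, rotate

    template = make_template()
    mean = to_preshape(template).points
    modes = make_mode_basis(template, config.K, config.basis_seed)
    delta = canonical_rotation_angle(mean)
    mean = rotate(mean, delta)
    modes = np.stack([rotate(m.reshape(-1, 2), delta).ravel() for m in modes])
    modes = _fix_mode_signs(modes)
    sds = config.mode_sds
    return ShapeModel(
        n_points=template.n_points,
        mean_shape=mean,
        modes=modes,
        mode_sds=sds,
        eigenvalues=sds**2,
        total_variance=float((sds**2).sum()),
        training_n=training_n or config.n_subjects,
        metadata={"source": "synthetic-generative", "basis_seed": config.basis_seed},
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def hwe_genotypes(n: int, eaf: float, seed_or_rng) -> tuple[np.ndarray, dict[str, int]]:
    """Draw ``n`` genotypes under Hardy–Weinberg proportions.

    Returns (dosages as floats in {0, 1, 2}, hard genotype counts) where
    ``n_aa`` counts effect-allele homozygotes.
    """
    if not 0.0 < eaf < 1.0:
        raise ValueError("eaf must lie in (0, 1)")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    q = eaf
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    g = rng.choice(3, size=n, p=probs)
    counts = {
        "n_AA": int((g == 0).sum()),
        "n_Aa": int((g == 1).sum()),
        "n_aa": int((g == 2).sum()),
    }
    return g.astype(float), counts


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _residual_sds(config: SimulationConfig) -> np.ndarray:
    """Per-mode residual SDs so the total standardised score variance is ~1."""
    var_g = np.zeros(config.K)
    for snp in config.snps:
        pq = 2.0 * snp.eaf * (1.0 - snp.eaf)
        for mode, beta in snp.betas.items():
            var_g[mode - 1] += beta**2 * pq
    return np.sqrt(np.maximum(1.0 - var_g, 0.1))


def _draw_covariates(config: SimulationConfig, ids: list[str],
                     rng: np.random.Generator) -> CovariateTable:
    p = config.covariates
    n = len(ids)
    sex = (rng.random(n) >= p.female_fraction).astype(int)  # 0 female, 1 male
    age = rng.normal(p.age_mean, p.age_sd, n)
    height = np.abs(rng.normal(p.height_mean, p.height_sd, n))
    weight = np.abs(rng.normal(p.weight_mean, p.weight_sd, n))
    df = pd.DataFrame(
        {"age": age, "sex": sex, "height": height, "weight": weight},
        index=pd.Index(ids, name="id"),
    )
    return CovariateTable(df)


def _render_landmarks(config: SimulationConfig, ids: list[str],
                      z: np.ndarray, rng: np.random.Generator
                      ) -> tuple[list[LandmarkSet], pd.DataFrame]:
    """Turn standardised scores into landmark files with noise + nuisance.

    Shapes are rendered from the same canonical-frame model that
    :func:`true_model` returns, so ledger scores and reference-model scores
    agree sign-for-sign.
    """
    tm = true_model(config)
    mean = tm.mean_vector
    modes = tm.modes
    sds = tm.mode_sds
    n = len(ids)
    shapes = mean + (z * sds) @ modes
    if config.landmark_noise_sd > 0:
        shapes = shapes + rng.normal(0.0, config.landmark_noise_sd, shapes.shape)
    theta = np.deg2rad(config.nuisance_rotation_deg)
    thetas = rng.uniform(-theta, theta, n)
    scales = rng.uniform(*config.nuisance_scale_range, n)
    trans = rng.uniform(-config.nuisance_translation,
                        config.nuisance_translation, (n, 2))
    out = []
    for i, sid in enumerate(ids):
        pts = shapes[i].reshape(-1, 2)
        c, s = np.cos(thetas[i]), np.sin(thetas[i])
        rot = np.array([[c, -s], [s, c]])
        pts = scales[i] * (pts @ rot.T) + trans[i]
        out.append(LandmarkSet(sid, pts))
    tf = pd.DataFrame(
        {"theta": thetas, "scale": scales, "tx": trans[:, 0], "ty": trans[:, 1]},
        index=pd.Index(ids, name="id"),
    )
    return out, tf


def _draw_scores(config: SimulationConfig, dosages: pd.DataFrame,
                 rng: np.random.Generator,
                 shared: np.ndarray | None = None,
                 rho: float = 0.0) -> np.ndarray:
    """Standardised true scores: offsets + genetic effects + residual.

    When ``shared`` (a (n, K) standard-normal latent block) is given, the
    residual is ``sqrt(rho) * shared + sqrt(1 - rho) * fresh`` so that
    overlapping subjects of two timepoints correlate at ~rho.
    """
    n = len(dosages)
    resid_sd = _residual_sds(config)
    e = rng.standard_normal((n, config.K))
    if shared is not None:
        e = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * e
    z = e * resid_sd
    for k, off in (config.score_offsets or {}).items():
        z[:, k - 1] += off
    for snp in config.snps:
        g = dosages[snp.snp_id].to_numpy()
        for mode, beta in snp.betas.items():
            z[:, mode - 1] += beta * g
    return z


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    subject_ids: list[str] | None = None,
    genotypes: GenotypeDosageTable | None = None,
    shared_latent: np.ndarray | None = None,
    rho: float = 0.0,
) -> tuple[CohortDataset, TruthLedger]:
    """Generate one cohort (optionally writing its files to ``out_dir``).

    ``subject_ids``/``genotypes``/``shared_latent`` allow a longitudinal
    caller to share subjects and genotypes across timepoints; by default all
    are drawn fresh from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ids = subject_ids or [
        f"{config.id_prefix}{i:06d}" for i in range(1, config.n_subjects + 1)
    ]
    n = len(ids)

    if genotypes is None:
        info_rows, dos_rows = [], []
        for snp in config.snps:
            g, counts = hwe_genotypes(n, snp.eaf, rng)
            info_rows.append({
                "snp_id": snp.snp_id,
                "effect_allele": snp.effect_allele,
                "other_allele": snp.other_allele,
                "eaf_declared": snp.eaf,
                **counts,
            })
            dos_rows.append(g)
        info = pd.DataFrame(
            info_rows, columns=["snp_id", "effect_allele", "other_allele",
                                "eaf_declared", "n_AA", "n_Aa", "n_aa"]
        ).set_index("snp_id")
        dosages = pd.DataFrame(dos_rows, index=info.index, columns=ids, dtype=float)
        genotypes = GenotypeDosageTable(info, dosages)
    dosage_by_subject = genotypes.dosages.T[[s.snp_id for s in config.snps]]

    z = _draw_scores(config, dosage_by_subject, rng, shared_latent, rho)
    covariates = _draw_covariates(config, ids, rng)
    landmarks, transforms = _render_landmarks(config, ids, z, rng)

    dataset = CohortDataset(landmarks, covariates, genotypes,
                            timepoint=config.timepoint)
    mode_cols = [f"mode{k}" for k in range(1, config.K + 1)]
    beta_mat = pd.DataFrame(
        0.0, index=[s.snp_id for s in config.snps], columns=mode_cols
    )
    beta_mat.index.name = "snp_id"
    for snp in config.snps:
        for mode, beta in snp.betas.items():
            beta_mat.loc[snp.snp_id, f"mode{mode}"] = beta
    ledger = TruthLedger(
        true_scores=pd.DataFrame(z, index=pd.Index(ids, name="id"),
                                 columns=mode_cols),
        dosages=dosage_by_subject.rename_axis("id"),
        transforms=transforms,
        betas=beta_mat,
        seed=config.seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_landmarks(landmarks, out / "landmarks.csv", dialect="wide")
        write_covariates(covariates, out / "covariates.tsv")
        write_dosages(genotypes, out / "dosages.tsv")
        config.to_yaml(out / "config.yaml")
        ledger.write(out / "truth")
    return dataset, ledger


def simulate_longitudinal(
    config_t1: SimulationConfig,
    config_t2: SimulationConfig,
    rho: float,
    seed: int | None = None,
    n_overlap: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[tuple[CohortDataset, TruthLedger], tuple[CohortDataset, TruthLedger]]:
    """Two cohorts with overlapping subjects sharing a latent score fraction.

    Overlapping subjects share genotypes exactly and a latent residual
    component with variance fraction ``rho``; partial attendance is simulated
    by giving each timepoint some subjects absent from the other.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    seed = config_t1.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n1, n2 = config_t1.n_subjects, config_t2.n_subjects
    if n_overlap is None:
        n_overlap = min(n1, n2) * 3 // 4
    if n_overlap > min(n1, n2):
        raise ValueError("overlap cannot exceed either cohort size")
    n_pool = n1 + n2 - n_overlap
    pool = [f"{config_t1.id_prefix}{i:06d}" for i in range(1, n_pool + 1)]
    ids1 = pool[:n1]
    ids2 = pool[:n_overlap] + pool[n1:]

    # pool-level genotypes, reused by both timepoints
    snps = config_t1.snps
    info_rows, dos_rows = [], []
    for snp in snps:
        g, counts = hwe_genotypes(n_pool, snp.eaf, rng)
        info_rows.append({
            "snp_id": snp.snp_id,
            "effect_allele": snp.effect_allele,
            "other_allele": snp.other_allele,
            "eaf_declared": snp.eaf,
            **counts,
        })
        dos_rows.append(g)
    info = pd.DataFrame(
        info_rows, columns=["snp_id", "effect_allele", "other_allele",
                            "eaf_declared", "n_AA", "n_Aa", "n_aa"]
    ).set_index("snp_id")
    pool_dosages = pd.DataFrame(dos_rows, index=info.index, columns=pool,
                                dtype=float)
    shared_pool = rng.standard_normal((n_pool, config_t1.K))
    pos = {sid: i for i, sid in enumerate(pool)}

    results = []
    for cfg, ids, sub_seed in ((config_t1, ids1, seed + 1),
                               (config_t2, ids2, seed + 2)):
        sub_dos = pool_dosages[ids].copy()
        sub_info = info.copy()
        # hard counts must describe this timepoint's subset of subjects
        sub_info["n_AA"] = (sub_dos == 0).sum(axis=1)
        sub_info["n_Aa"] = (sub_dos == 1).sum(axis=1)
        sub_info["n_aa"] = (sub_dos == 2).sum(axis=1)
        geno = GenotypeDosageTable(sub_info, sub_dos)
        shared = shared_pool[[pos[s] for s in ids]]
        cfg_run = SimulationConfig(**{**asdict(cfg),
                                      "covariates": cfg.covariates,
                                      "snps": cfg.snps,
                                      "seed": sub_seed})
        sub_out = None
        if out_dir is not None:
            sub_out = Path(out_dir) / cfg.timepoint
        results.append(simulate_cohort(
            cfg_run, out_dir=sub_out, subject_ids=ids, genotypes=geno,
            shared_latent=shared, rho=rho,
        ))
    return results[0], results[1]
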