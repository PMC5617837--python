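"""Seeded generators for every input the analysis pipelines consume.

The generators emulate the study design the package targets: two myocardial
regions (ischemic, remote) sampled at four reperfusion time points against
baseline, quantified by 8-plex isobaric labeling of pooled extracts with a
three-level noise hierarchy (scan, peptide, protein), plus label-free
per-animal intensities, targeted-proteomics chromatograms, and per-animal
wall-thickening records moment-matched to group summaries. Every generator
is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryAnnotation
from .cmr import GroupSummary, ISCHEMIC_SEGMENTS, REMOTE_SEGMENTS
from .labelfree import tryptic_peptides
from .prm import Chromatogram

__all__ = [
    "DistSpec",
    "CategoryEffect",
    "EffectArchetype",
    "ARCHETYPES",
    "SimulationConfig",
    "generate_scan_table",
    "category_annotations",
    "generate_proteome",
    "generate_labelfree_intensities",
    "generate_chromatograms",
    "generate_cmr_records",
]

TIMEPOINTS = ("R-120min", "R-24h", "R-Day4", "R-Day7")
REGIONS = ("ischemic", "remote")


@dataclass(frozen=True)
class EffectArchetype:
    """Signed per-timepoint multipliers of a category's coordinated effect."""

    name: str
    template: tuple[float, float, float, float]


#: The five time-course archetypes, mapping 1:1 onto clusters a-e:
#: sustained early upregulation, early downregulation that recovers, late
#: upregulation peaking at day 7, progressive downregulation, and a
#: transient early excursion.
ARCHETYPES: dict[str, EffectArchetype] = {
    a.name: a
    for a in (
        EffectArchetype("early_sustained_up", (1.0, 1.0, 1.0, 1.0)),
        EffectArchetype("early_down_recover", (-1.0, -1.0, -0.5, 0.0)),
        EffectArchetype("late_up_peak_d7", (0.0, 0.0, 0.5, 1.0)),
        EffectArchetype("late_down", (0.0, -0.5, -0.8, -1.0)),
        EffectArchetype("transient_early", (1.0, 1.0, 0.3, 0.0)),
    )
}


@dataclass(frozen=True)
class DistSpec:
    """Count distribution spec; geometric truncated at 1 (support 1, 2, ...)."""

    kind: str = "geometric"
    mean: float = 2.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, int(round(self.mean)))
        if self.kind == "geometric":
            if self.mean < 1:
                raise ValueError("geometric mean must be >= 1")
            return rng.geometric(1.0 / self.mean, size=size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class CategoryEffect:
    """A coordinated category effect: ``delta`` is in units of each member
    protein's total null standard deviation (so the expected member Zq is
    delta x template and the expected Zc is sqrt(size) x delta x template).
    ``region=None`` applies the effect in every region."""

    category_id: str
    size: int
    archetype: str
    delta: float
    region: str | None = None

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("category size must be >= 1")
        if self.archetype not in ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.archetype!r}; choose from {sorted(ARCHETYPES)}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters of the synthetic isobaric experiment.

    Noise scales are log2 standard deviations. The scan-level SD may grow
    at low spectral intensity as sigma_S(I) = sigma_S + sigma_S_slope/sqrt(I)
    (homoscedastic by default).
    """

    n_proteins: int = 5000
    peptides_per_protein: DistSpec = field(default_factory=lambda: DistSpec("geometric", 3.0))
    scans_per_peptide: DistSpec = field(default_factory=lambda: DistSpec("geometric", 2.0))
    sigma_S: float = 0.2
    sigma_S_slope: float = 0.0
    sigma_P: float = 0.3
    sigma_Q: float = 0.5
    categories: tuple[CategoryEffect, ...] = ()
    n_null_categories: int = 0
    null_category_size: int = 10
    timepoints: tuple[str, ...] = TIMEPOINTS
    regions: tuple[str, ...] = REGIONS
    n_animals_per_group: int = 5
    lf_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for name in ("sigma_S", "sigma_S_slope", "sigma_P", "sigma_Q", "lf_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.categories and len(self.timepoints) != 4:
            raise ValueError("archetype templates require exactly 4 ordered timepoints")
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return [(r, t) for r in self.regions for t in self.timepoints]


def _protein_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:05d}" for i in range(n)])


def _rngs(config: SimulationConfig, n: int):
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(config.seed).spawn(n)]


def _memberships(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Category -> member protein indices; disjoint assignment from a
    seed-determined shuffle (null filler categories appended)."""
    effects = list(config.categories) + [
        CategoryEffect(f"null{i:04d}", config.null_category_size, "early_sustained_up", 0.0)
        for i in range(config.n_null_categories)
    ]
    total = sum(e.size for e in effects)
    if total > config.n_proteins:
        raise ValueError(
            f"disjoint categories need {total} proteins but only {config.n_proteins} exist"
        )
    order = rng.permutation(config.n_proteins)
    out, pos = {}, 0
    for e in effects:
        out[e.category_id] = np.sort(order[pos : pos + e.size])
        pos += e.size
    return out


def category_annotations(config: SimulationConfig) -> list[CategoryAnnotation]:
    """The GMT-ready annotations matching :func:`generate_scan_table`'s effects."""
    rng_members = _rngs(config, 3)[1]
    ids = _protein_ids(config.n_proteins)
    effects = {e.category_id: e for e in config.categories}
    out = []
    for cat, idx in _memberships(config, rng_members).items():
        eff = effects.get(cat)
        desc = (
            f"{eff.archetype} delta={eff.delta:g}" if eff is not None and eff.delta else "null"
        )
        out.append(CategoryAnnotation(cat, desc, tuple(ids[idx])))
    return out


def generate_scan_table(config: SimulationConfig) -> pd.DataFrame:
    """Scan-level log2 ratios for the full region x timepoint design.

    Each scan row carries x_s = delta_q(condition) + e_P(peptide, condition)
    + e_S(scan, condition); protein-level true changes are the sum of the
    category effect (scaled by the protein's total null SD, see
    :class:`CategoryEffect`) and a protein scatter ~N(0, sigma_Q^2). Spectral
    intensities are log-uniform over 1e5..1e8. Identical configurations and
    seeds produce identical tables.
    """
    rng_struct, rng_members, rng_noise = _rngs(config, 3)
    nq = config.n_proteins
    proteins = _protein_ids(nq)

    k_pep = config.peptides_per_protein.sample(rng_struct, nq)
    pep_protein = np.repeat(np.arange(nq), k_pep)  # protein index per peptide
    n_pep = pep_protein.size
    pep_rank = np.concatenate([np.arange(k) for k in k_pep])
    n_scan_per_pep = config.scans_per_peptide.sample(rng_struct, n_pep)
    scan_pep = np.repeat(np.arange(n_pep), n_scan_per_pep)  # peptide index per scan
    n_scan = scan_pep.size
    intensity = 10.0 ** rng_struct.uniform(5.0, 8.0, size=n_scan)
    sigma_s = config.sigma_S + config.sigma_S_slope / np.sqrt(intensity)

    # theoretical quantification variance per protein, used to express
    # category effects in units of the total null SD
    v_p_theory = np.bincount(scan_pep, weights=1.0 / np.maximum(sigma_s, 1e-9) ** 2, minlength=n_pep)
    v_p_theory = 1.0 / v_p_theory
    w_prot = np.bincount(pep_protein, weights=1.0 / (v_p_theory + config.sigma_P**2), minlength=nq)
    total_sd = np.sqrt(config.sigma_Q**2 + 1.0 / w_prot)

    members = _memberships(config, rng_members)
    tp_index = {t: i for i, t in enumerate(config.timepoints)}

    scan_ids = np.array([f"S{i:07d}" for i in range(n_scan)])
    pep_ids = np.array(
        [f"{proteins[q]}_pep{r}" for q, r in zip(pep_protein, pep_rank)]
    )
    x_parts, region_parts, tp_parts = [], [], []
    for region in config.regions:
        for tp in config.timepoints:
            delta = rng_noise.normal(0.0, config.sigma_Q, size=nq)
            for eff in config.categories:
                if eff.region is not None and eff.region != region:
                    continue
                idx = members[eff.category_id]
                shift = eff.delta * ARCHETYPES[eff.archetype].template[tp_index[tp]]
                delta[idx] += shift * total_sd[idx]
            e_p = rng_noise.normal(0.0, config.sigma_P, size=n_pep)
            e_s = rng_noise.normal(0.0, 1.0, size=n_scan) * sigma_s
            x_parts.append(delta[pep_protein[scan_pep]] + e_p[scan_pep] + e_s)
            region_parts.append(region)
            tp_parts.append(tp)
    n_cond = len(x_parts)
    return pd.DataFrame(
        {
            "scan_id": np.tile(scan_ids, n_cond),
            "peptide": np.tile(pep_ids[scan_pep], n_cond),
            "protein": np.tile(proteins[pep_protein[scan_pep]], n_cond),
            "region": np.repeat(np.array(region_parts, dtype=object), n_scan),
            "timepoint": np.repeat(np.array(tp_parts, dtype=object), n_scan),
            "log2_ratio": np.concatenate(x_parts),
            "intensity": np.tile(intensity, n_cond),
        }
    )


# ---------------------------------------------------------------------------
# label-free


_AA_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.5, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 6.0, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 4.0,
    "R": 5.5, "S": 6.6, "T": 5.3, "V": 6.9, "W": 1.1, "Y": 2.9,
}


def generate_proteome(n_proteins: int, seed: int, mean_length: int = 300) -> dict[str, str]:
    """Random protein catalog with natural-ish residue frequencies."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(_AA_FREQ))
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    ids = _protein_ids(n_proteins)
    lengths = np.maximum(50, rng.poisson(mean_length, size=n_proteins))
    return {
        pid: "".join(rng.choice(letters, size=length, p=probs))
        for pid, length in zip(ids, lengths)
    }


def generate_labelfree_intensities(
    config: SimulationConfig,
    proteome: Mapping[str, str],
    fold_changes: Mapping[str, Mapping[str, float] | float] | None = None,
) -> pd.DataFrame:
    """Per-animal, per-peptide positive intensities for label-free iBAQ.

    Peptides are the tryptic 7-30mers of each catalog sequence; intensities
    are log-normal around protein abundance x fixed peptide response x
    2^(group log2 fold change), with log2 SD ``config.lf_sigma`` (zero SD
    reproduces the configured means exactly). ``fold_changes`` maps protein
    id to either one log2 FC for every post-baseline group or a per-group
    mapping. Groups are baseline plus the config's timepoints, with
    ``n_animals_per_group`` animals each.
    """
    if not proteome:
        raise ValueError("empty proteome")
    rng_struct, rng_noise = _rngs(config, 2)[:2]
    fold_changes = fold_changes or {}
    unknown = set(fold_changes) - set(proteome)
    if unknown:
        raise ValueError(f"fold changes for proteins without sequences: {sorted(unknown)[:5]}")
    groups = ("baseline",) + tuple(config.timepoints)
    rows = {k: [] for k in ("animal", "group", "protein", "peptide", "intensity")}
    for pid in sorted(proteome):
        peptides = tryptic_peptides(proteome[pid])
        abund = rng_struct.normal(20.0, 2.0)
        resp = rng_struct.normal(0.0, 1.0, size=len(peptides))
        if not peptides:
            continue
        fc_spec = fold_changes.get(pid, 0.0)
        for group in groups:
            if isinstance(fc_spec, Mapping):
                fc = float(fc_spec.get(group, 0.0))
            else:
                fc = 0.0 if group == "baseline" else float(fc_spec)
            for a in range(config.n_animals_per_group):
                noise = (
                    rng_noise.normal(0.0, config.lf_sigma, size=len(peptides))
                    if config.lf_sigma > 0
                    else 0.0
                )
                log2_i = abund + resp + fc + noise
                rows["animal"].extend([f"{group}_a{a + 1}"] * len(peptides))
                rows["group"].extend([group] * len(peptides))
                rows["protein"].extend([pid] * len(peptides))
                rows["peptide"].extend(peptides)
                rows["intensity"].extend(2.0**log2_i)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chromatograms


def generate_chromatograms(
    peptides: Sequence[str],
    n_transitions: int,
    peak: tuple[float, float, float],
    noise_sd: float,
    seed: int,
    t_start: float = 0.0,
    t_end: float = 60.0,
    dt: float = 0.1,
    amplitude_scale: Mapping[str, float] | None = None,
) -> list[Chromatogram]:
    """Gaussian elution peaks plus white noise on a uniform time grid.

    ``peak`` is (center s, width sigma s, amplitude); each of a peptide's
    transitions alternates y-/b-series labels. ``amplitude_scale``
    optionally multiplies the amplitude per peptide (e.g. to emulate
    abundance drops). Negative noisy samples are clipped at zero.
    """
    center, width, amplitude = peak
    if width <= 0:
        raise ValueError("peak width must be positive")
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be >= 0")
    t = np.arange(t_start, t_end + dt / 2, dt)
    if t.size == 0:
        raise ValueError("empty time grid")
    rng = np.random.default_rng(seed)
    shape = np.exp(-((t - center) ** 2) / (2.0 * width**2))
    out = []
    for pep in peptides:
        amp = amplitude * (amplitude_scale.get(pep, 1.0) if amplitude_scale else 1.0)
        for j in range(n_transitions):
            series = "y" if j % 2 == 0 else "b"
            trace = amp * shape
            if noise_sd > 0:
                trace = np.maximum(trace + rng.normal(0.0, noise_sd, size=t.size), 0.0)
            out.append(
                Chromatogram(
                    peptide=pep,
                    transition=f"{pep}_{series}{j + 3}",
                    ion=f"{series}{j + 3}",
                    times=t,
                    intensities=trace,
                )
            )
    return out


# ---------------------------------------------------------------------------
# CMR


def generate_cmr_records(targets: Sequence[GroupSummary], seed: int) -> pd.DataFrame:
    """Per-animal wall-thickness records whose regional SWT sample moments
    match each target group summary exactly (affine moment matching).

    End-diastolic thickness is fixed at 10 mm and end-systolic thickness set
    so that SWT reproduces the matched values; both designated segments of
    each region carry the animal's regional value.
    """
    rng = np.random.default_rng(seed)
    segments = {"ischemic": ISCHEMIC_SEGMENTS, "remote": REMOTE_SEGMENTS}
    rows = {k: [] for k in ("animal", "group", "region", "phase", "segment", "edwt_mm", "eswt_mm")}
    for tgt in targets:
        if tgt.sd > 0 and tgt.n < 2:
            raise ValueError("a nonzero target SD requires n >= 2")
        if tgt.n >= 2 and tgt.sd > 0:
            z = rng.normal(size=tgt.n)
            while np.std(z, ddof=1) == 0:  # pragma: no cover - probability zero
                z = rng.normal(size=tgt.n)
            swt = tgt.mean + tgt.sd * (z - z.mean()) / np.std(z, ddof=1)
        else:
            swt = np.full(tgt.n, tgt.mean)
        edwt = 10.0
        for i, value in enumerate(swt):
            for seg in segments.get(tgt.region, ("segment1", "segment2")):
                rows["animal"].append(f"{tgt.group}_a{i + 1}")
                rows["group"].append(tgt.group)
                rows["region"].append(tgt.region)
                rows["phase"].append(tgt.phase)
                rows["segment"].append(seg)
                rows["edwt_mm"].append(edwt)
                rows["eswt_mm"].append(edwt * (1.0 + value / 100.0))
    return pd.DataFrame(rows)
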