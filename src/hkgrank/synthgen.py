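"""Synthetic multi-study expression collections with known stability structure.

Emulates a collection of independent Affymetrix-style microarray studies
(probe-level PM/MM intensities) plus RNA-seq-style count matrices, with three
gene archetypes embedded as ground truth:

* ``housekeeping`` — low biological variance everywhere, no condition effects;
* ``responsive``   — large log2 shifts under the treated condition in a random
  subset of studies, moderate baseline variance;
* ``noisy``        — large biological variance, no systematic effects.

The probe layer adds per-probe affinities (constant across arrays, as on a real
chip), per-cell measurement noise, an additive optical background per array,
and a cross-hybridization-shaped mismatch channel.  A configurable fraction of
genes is covered by two probe sets and a fraction of probe sets maps to two
genes, to exercise the probe-to-gene collapse rules downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARCHETYPES = ("housekeeping", "responsive", "noisy")


@dataclass(frozen=True)
class NoiseParams:
    """Noise / effect-size knobs for the generator.

    All scales are log2 expression units unless noted.  Defaults describe a
    plausible multi-condition microarray compendium: tight housekeeping genes,
    regulated genes with at least two-fold condition shifts in ~30% of studies,
    and a per-probe measurement layer typical of array technology.
    """

    hk_noise: tuple[float, float] = (0.05, 0.15)
    responsive_noise: tuple[float, float] = (0.25, 0.6)
    noisy_noise: tuple[float, float] = (0.5, 1.2)
    probe_noise_sd: float = 0.25
    probe_affinity_sd: float = 0.5
    effect_range: tuple[float, float] = (1.0, 3.0)
    p_affect: float = 0.3
    #: per-array additive optical background, linear units; None disables it
    background_range: tuple[float, float] | None = (20.0, 60.0)
    background_cell_sd: float = 5.0
    mm_fraction: float = 0.6
    mm_exponent: float = 0.9


@dataclass
class SyntheticTruth:
    """Ground-truth stability structure of a generated collection."""

    table: pd.DataFrame            # index gene_id: archetype, base_level, noise_sd
    study_effects: pd.DataFrame    # gene x study log2 shift (0 for housekeeping)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def genes_of(self, archetype: str) -> list[str]:
        if archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {archetype!r}")
        return list(self.table.index[self.table["archetype"] == archetype])

    def validate(self, hk_noise_bound: float = 0.15) -> None:
        t = self.table
        if set(t["archetype"]) - set(ARCHETYPES):
            raise ValueError("archetype column contains unknown labels")
        hk = t["archetype"] == "housekeeping"
        if not (self.study_effects.loc[t.index[hk]].to_numpy() == 0).all():
            raise ValueError("housekeeping genes must have zero study effects")
        if not (t.loc[hk, "noise_sd"] <= hk_noise_bound + 1e-12).all():
            raise ValueError("housekeeping noise_sd exceeds the stated bound")
        resp = t.index[t["archetype"] == "responsive"]
        eff = self.study_effects.loc[resp].abs().to_numpy()
        if len(resp) and not (eff.max(axis=1) >= 1.0 - 1e-12).all():
            raise ValueError("every responsive gene needs one |effect| >= 1")


@dataclass
class StudyManifest:
    study_id: str
    n_samples: int
    condition_labels: list[str]
    has_raw: bool = True
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if len(self.condition_labels) != self.n_samples:
            raise ValueError("condition_labels length must equal n_samples")


@dataclass
class ProbeAnnotation:
    """Maps probeset_id -> tuple of gene_ids (multi-gene probesets allowed)."""

    mapping: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for ps, genes in self.mapping.items():
            if len(genes) < 1:
                raise ValueError(f"probeset {ps} maps to no gene")

    def genes_for(self, probeset_id: str) -> tuple[str, ...]:
        return self.mapping[probeset_id]


@dataclass
class ProbeIntensityMatrix:
    """Raw probe-level intensities for one study (linear scale, PM > 0)."""

    study_id: str
    probeset_ids: list[str]
    probes_per_set: int
    pm: np.ndarray                  # (n_probesets, probes_per_set, n_samples)
    sample_ids: list[str]
    mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_ps, p, n = self.pm.shape
        if n_ps != len(self.probeset_ids) or p != self.probes_per_set:
            raise ValueError("pm shape inconsistent with probeset ids / probes_per_set")
        if n != len(self.sample_ids):
            raise ValueError("pm shape inconsistent with sample ids")
        if not (self.pm > 0).all():
            raise ValueError("all PM intensities must be strictly positive")
        if self.mm is not None and self.mm.shape != self.pm.shape:
            raise ValueError("mm must have the same shape as pm")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _check_fraction(name: str, value: float) -> None:
    if not 0 < value < 1:
        raise ValueError(f"{name} must lie strictly between 0 and 1, got {value}")


def generate_collection(
    n_studies: int = 30,
    n_genes: int = 2000,
    frac_housekeeping: float = 0.02,
    probes_per_set: int = 11,
    noise: NoiseParams = NoiseParams(),
    seed: int | np.random.SeedSequence = 1,
    n_samples_range: tuple[int, int] = (4, 24),
    frac_responsive: float = 0.30,
    frac_multiprobe: float = 0.10,
    frac_multigene_probe: float = 0.05,
) -> tuple[list[ProbeIntensityMatrix], ProbeAnnotation, SyntheticTruth, list[StudyManifest]]:
    """Generate a fully reproducible collection of synthetic studies.

    Linear-scale PM = 2^(base + study_effect * condition + biological noise +
    probe affinity + measurement noise) plus an additive per-array background;
    MM = mm_fraction * PM_signal^mm_exponent plus background.  Each study has a
    two-group condition design with 4-24 samples by default.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    if n_genes < 20:
        raise ValueError("n_genes must be >= 20")
    if probes_per_set < 1:
        raise ValueError("probes_per_set must be >= 1")
    _check_fraction("frac_housekeeping", frac_housekeeping)
    _check_fraction("frac_responsive", frac_responsive)
    if frac_housekeeping + frac_responsive >= 1:
        raise ValueError("archetype fractions must sum below 1")

    rng = np.random.default_rng(seed)
    gw = max(4, len(str(n_genes)))
    gene_ids = np.array([f"G{i:0{gw}d}" for i in range(n_genes)])

    # archetype partition (covers all genes exactly once)
    n_hk = max(1, round(frac_housekeeping * n_genes))
    n_resp = max(1, round(frac_responsive * n_genes))
    perm = rng.permutation(n_genes)
    archetype = np.full(n_genes, "noisy", dtype=object)
    archetype[perm[:n_hk]] = "housekeeping"
    archetype[perm[n_hk:n_hk + n_resp]] = "responsive"

    base = rng.uniform(5.0, 12.0, n_genes)
    # housekeeping genes are highly expressed, as real reference genes are
    base[archetype == "housekeeping"] = rng.uniform(8.0, 12.0, n_hk)

    noise_sd = np.empty(n_genes)
    for arch, rng_pair in (
        ("housekeeping", noise.hk_noise),
        ("responsive", noise.responsive_noise),
        ("noisy", noise.noisy_noise),
    ):
        mask = archetype == arch
        noise_sd[mask] = rng.uniform(*rng_pair, mask.sum())

    study_ids = [f"ST{j:03d}" for j in range(n_studies)]
    lo, hi = n_samples_range
    n_samples = rng.integers(lo, hi + 1, n_studies)

    # per-study condition effects for responsive genes
    effects = np.zeros((n_genes, n_studies))
    resp_idx = np.flatnonzero(archetype == "responsive")
    affected = rng.random((len(resp_idx), n_studies)) < noise.p_affect
    magnitude = rng.uniform(*noise.effect_range, (len(resp_idx), n_studies))
    sign = rng.choice([-1.0, 1.0], (len(resp_idx), n_studies))
    # guarantee every responsive gene is hit at least once
    forced = rng.integers(0, n_studies, len(resp_idx))
    affected[np.arange(len(resp_idx)), forced] = True
    effects[resp_idx] = affected * sign * np.maximum(magnitude, 1.0)

    # probe sets: one per gene, plus a second for a fraction of genes
    n_extra = round(frac_multiprobe * n_genes)
    extra_genes = rng.choice(n_genes, n_extra, replace=False)
    ps_gene = np.concatenate([np.arange(n_genes), extra_genes])
    n_ps = len(ps_gene)
    pw = max(5, len(str(n_ps)))
    probeset_ids = [f"PS{i:0{pw}d}" for i in range(n_ps)]

    mapping: dict[str, list[str]] = {
        ps: [gene_ids[g]] for ps, g in zip(probeset_ids, ps_gene)
    }
    n_multi = round(frac_multigene_probe * n_ps)
    multi_ps = rng.choice(n_ps, n_multi, replace=False)
    for i in multi_ps:
        other = int(rng.integers(0, n_genes - 1))
        if other >= ps_gene[i]:
            other += 1
        mapping[probeset_ids[i]].append(gene_ids[other])
    annotation = ProbeAnnotation({k: tuple(v) for k, v in mapping.items()})

    affinity = rng.normal(0.0, noise.probe_affinity_sd, (n_ps, probes_per_set))

    matrices: list[ProbeIntensityMatrix] = []
    manifests: list[StudyManifest] = []
    for s, sid in enumerate(study_ids):
        n = int(n_samples[s])
        cond = (np.arange(n) >= n // 2).astype(float)   # two groups per study
        labels = ["treated" if c else "control" for c in cond]
        sample_ids = [f"{sid}_S{j:02d}" for j in range(n)]

        bio = rng.normal(0.0, 1.0, (n_genes, n)) * noise_sd[:, None]
        logsig_gene = base[:, None] + effects[:, [s]] * cond[None, :] + bio
        x = (
            logsig_gene[ps_gene][:, None, :]
            + affinity[:, :, None]
            + rng.normal(0.0, noise.probe_noise_sd, (n_ps, probes_per_set, n))
        )
        pm_signal = np.exp2(x)
        mm_signal = noise.mm_fraction * pm_signal ** noise.mm_exponent
        if noise.background_range is not None:
            bg = rng.uniform(*noise.background_range, n)
            pm_bg = np.maximum(
                bg[None, None, :]
                + rng.normal(0.0, noise.background_cell_sd, pm_signal.shape),
                1.0,
            )
            mm_bg = np.maximum(
                bg[None, None, :]
                + rng.normal(0.0, noise.background_cell_sd, pm_signal.shape),
                1.0,
            )
        else:
            pm_bg = 0.0
            mm_bg = 0.0
        pm = pm_signal + pm_bg
        mm = np.maximum(mm_signal + mm_bg, 1e-6)

        matrices.append(
            ProbeIntensityMatrix(sid, list(probeset_ids), probes_per_set, pm,
                                 sample_ids, mm=mm)
        )
        manifests.append(StudyManifest(sid, n, labels))

    truth = SyntheticTruth(
        table=pd.DataFrame(
            {"archetype": archetype, "base_level": base, "noise_sd": noise_sd},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        study_effects=pd.DataFrame(effects, index=pd.Index(gene_ids, name="gene_id"),
                                   columns=study_ids),
    )
    truth.validate(hk_noise_bound=noise.hk_noise[1])
    return matrices, annotation, truth, manifests


def filter_studies(manifests: list[StudyManifest]) -> list[StudyManifest]:
    """Keep studies with more than three samples, no duplication, raw data.

    Order is preserved; an empty input yields an empty output.  Idempotent.
    """
    return [
        m for m in manifests
        if m.n_samples > 3 and m.duplicate_of is None and m.has_raw
    ]


def generate_counts(
    truth: SyntheticTruth,
    n_samples: int,
    lib_sizes: float | np.ndarray,
    seed: int | np.random.SeedSequence,
    dispersion: float = 0.05,
    p_affect: float = 0.3,
    effect_range: tuple[float, float] = (1.0, 3.0),
) -> pd.DataFrame:
    """RNA-seq-style gene x sample counts from the same ground truth.

    Counts are negative-binomial (gamma-Poisson) with mean proportional to
    2^(base + condition effect + biological noise) times the library size.
    A fresh condition-effect realization is drawn for responsive genes, so the
    matrix behaves like a held-out validation study.  ``dispersion == 0``
    returns the rounded expected means (degenerate limit).
    """
    lib = np.broadcast_to(np.asarray(lib_sizes, dtype=float), (n_samples,)).copy()
    if (lib <= 0).any():
        raise ValueError("library sizes must be strictly positive")
    rng = np.random.default_rng(seed)
    t = truth.table
    n_genes = len(t)
    base = t["base_level"].to_numpy()
    noise_sd = t["noise_sd"].to_numpy()
    cond = (np.arange(n_samples) >= n_samples // 2).astype(float)

    effects = np.zeros(n_genes)
    resp = (t["archetype"] == "responsive").to_numpy()
    hit = rng.random(n_genes) < p_affect
    mag = rng.uniform(*effect_range, n_genes)
    sgn = rng.choice([-1.0, 1.0], n_genes)
    effects[resp & hit] = (mag * sgn)[resp & hit]

    x = (
        base[:, None]
        + effects[:, None] * cond[None, :]
        + rng.normal(0.0, 1.0, (n_genes, n_samples)) * noise_sd[:, None]
    )
    rel = np.exp2(x)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    if dispersion == 0:
        counts = np.rint(mu)
    elif dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    else:
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        counts = rng.poisson(lam).astype(float)
    samples = [f"V_S{j:02d}" for j in range(n_samples)]
    return pd.DataFrame(counts.astype(np.int64), index=t.index.copy(), columns=samples)


# ---------------------------------------------------------------------------
# plain-TSV persistence

def _probe_row_ids(probeset_ids: list[str], probes_per_set: int) -> list[str]:
    return [f"{ps}_{p + 1:02d}" for ps in probeset_ids for p in range(probes_per_set)]


def write_collection(
    out_dir: str | Path,
    matrices: list[ProbeIntensityMatrix],
    annotation: ProbeAnnotation,
    truth: SyntheticTruth,
    manifests: list[StudyManifest],
) -> Path:
    """Write a collection as plain TSV files under ``out_dir``."""
    out = Path(out_dir)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    for mat in matrices:
        sdir = out / "studies" / mat.study_id
        sdir.mkdir(exist_ok=True)
        rows = _probe_row_ids(mat.probeset_ids, mat.probes_per_set)
        for name, arr in (("pm", mat.pm), ("mm", mat.mm)):
            if arr is None:
                continue
            df = pd.DataFrame(arr.reshape(len(rows), -1), index=rows,
                              columns=mat.sample_ids)
            df.rename_axis("probe").to_csv(sdir / f"{name}.tsv", sep="\t",
                                           float_format="%.4f")
    ann = pd.DataFrame(
        {"probeset_id": list(annotation.mapping),
         "gene_ids": [",".join(v) for v in annotation.mapping.values()]}
    )
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
    truth.table.to_csv(out / "truth.tsv", sep="\t", float_format="%.6f")
    truth.study_effects.to_csv(out / "study_effects.tsv", sep="\t",
                               float_format="%.6f")
    man = pd.DataFrame(
        {
            "study_id": [m.study_id for m in manifests],
            "n_samples": [m.n_samples for m in manifests],
            "has_raw": [m.has_raw for m in manifests],
            "duplicate_of": [m.duplicate_of or "" for m in manifests],
            "condition_labels": [",".join(m.condition_labels) for m in manifests],
        }
    )
    man.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ProbeAnnotation(
        {r.probeset_id: tuple(r.gene_ids.split(",")) for r in df.itertuples()}
    )


def read_truth(dir_path: str | Path) -> SyntheticTruth:
    d = Path(dir_path)
    table = pd.read_csv(d / "truth.tsv", sep="\t", index_col="gene_id")
    effects = pd.read_csv(d / "study_effects.tsv", sep="\t", index_col="gene_id")
    return SyntheticTruth(table=table, study_effects=effects)


def read_manifests(path: str | Path) -> list[StudyManifest]:
    df = pd.read_csv(path, sep="\t", dtype={"duplicate_of": str})
    out = []
    for r in df.itertuples():
        dup = None if pd.isna(r.duplicate_of) or r.duplicate_of == "" else r.duplicate_of
        out.append(
            StudyManifest(r.study_id, int(r.n_samples),
                          str(r.condition_labels).split(","), bool(r.has_raw), dup)
        )
    return out


def read_probe_matrix(study_dir: str | Path, study_id: str | None = None) -> ProbeIntensityMatrix:
    d = Path(study_dir)
    pm_df = pd.read_csv(d / "pm.tsv", sep="\t", index_col="probe")
    rows = list(pm_df.index)
    probeset_ids = list(dict.fromkeys(r.rsplit("_", 1)[0] for r in rows))
    p = len(rows) // len(probeset_ids)
    pm = pm_df.to_numpy().reshape(len(probeset_ids), p, -1)
    mm = None
    if (d / "mm.tsv").exists():
        mm = pd.read_csv(d / "mm.tsv", sep="\t", index_col="probe").to_numpy()
        mm = mm.reshape(pm.shape)
    return ProbeIntensityMatrix(study_id or d.name, probeset_ids, p, pm,
                                list(pm_df.columns), mm=mm)
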