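"""Synthetic probe-level datasets with planted expression-pattern classes.

The generator emulates the study design downstream stages expect: four
treatment groups (AL, CR, F2, SK) with unbalanced replication (6/6/4/6 arrays
by default), probe sets of 2–3 probes, Gaussian log2 intensities and gene-wise
variances drawn from a scaled inverse-chi-square prior — the generative model
under which empirical-Bayes variance moderation is exact.

Seven planted effect classes give every downstream stage a ground-truth
oracle:

``null``
    no treatment effect;
``switching_up_in_fast`` / ``switching_down_in_fast``
    opposite-sign offsets on the fed (F2) and fasting (SK) days of the
    intermittent-fasting cycle, mimicking genes that track the metabolic
    switch;
``chronic_up`` / ``chronic_down``
    equal same-sign offsets on both IF days relative to the ad libitum
    reference, with CR at the AL level — chronically changed relative to
    both control regimens;
``chronic_and_switching_up``
    same-sign offsets with the fasting-day offset exceeding the fed-day
    offset, so the gene is both chronically changed and switching;
``cr_responsive``
    restriction-responsive genes offset (same random sign per gene) in both
    low-energy states (CR and the fasting day) — the dominant
    fed-vs-underfed axis that makes the sample dendrogram separate {AL, F2}
    from {CR, SK}, mirroring the lipid/carbohydrate-metabolism bulk of a
    filtered liver IF gene set.

The five non-null effect shapes form four well-separated profile archetypes
(the two switching directions, chronic-up together with
chronic-and-switching, and chronic-down), so a four-cluster cut of the
filtered genes has a well-defined planted answer; restriction-responsive
genes co-cluster with whichever archetype they fall nearest.

Every gene's generating class, per-treatment offsets and true variance are
returned as a ``PlantedTruth`` table, the recovery oracle for all tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .io import TRAIT_NAMES
from .params import TREATMENTS

PATTERN_CLASSES: tuple[str, ...] = (
    "null",
    "switching_up_in_fast",
    "switching_down_in_fast",
    "chronic_up",
    "chronic_down",
    "chronic_and_switching_up",
    "cr_responsive",
)

#: Default class mix, chosen to mirror the composition of a filtered liver
#: IF-transcriptome gene set: restriction-responsive (fed-vs-underfed) genes
#: dominate, strict switching and chronic classes are small.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "null": 0.54,
    "cr_responsive": 0.30,
    "chronic_up": 0.04,
    "chronic_down": 0.04,
    "switching_up_in_fast": 0.03,
    "switching_down_in_fast": 0.03,
    "chronic_and_switching_up": 0.02,
}

_MIN_FC_LOG2 = float(np.log2(1.4))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic dataset generator.

    Parameters
    ----------
    n_per_treatment
        Arrays per treatment group (default AL:6, CR:6, F2:4, SK:6 — the
        post-QC design of the emulated study).
    n_probesets
        Number of probe sets / genes (default 2000, a desk-scale stand-in for
        the 20,771 probe sets of the full array).
    probes_per_set_weights
        Probability of a probe set having 2 vs 3 probes.
    baseline_mean, baseline_sd
        Distribution of gene baseline log2 intensities.
    var_prior_d0, var_prior_s0sq
        Scaled inverse-chi-square prior of gene-wise variances:
        sigma² = d0·s0² / chi²(d0).
    class_proportions
        Mix of planted pattern classes; must sum to 1.
    effect_size_log2
        Minimum planted |offset| in log2 units (default 0.8); per-gene
        magnitudes are drawn uniformly from [effect, effect + 0.4].
    probe_bias_sd
        SD of the per-probe constant additive bias.
    array_shift_sd
        SD of an optional global per-array intensity shift (default 0 = off),
        for exercising the optional between-array normalization stage.
    seed
        Random seed; identical config + seed gives bit-identical output.
    """

    n_per_treatment: dict = field(
        default_factory=lambda: {"AL": 6, "CR": 6, "F2": 4, "SK": 6}
    )
    n_probesets: int = 2000
    probes_per_set_weights: dict = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    var_prior_d0: float = 4.0
    var_prior_s0sq: float = 0.05
    class_proportions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size_log2: float = 0.8
    probe_bias_sd: float = 0.3
    array_shift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_proportions) - set(PATTERN_CLASSES)
        if unknown:
            raise ValidationError(f"unknown pattern class(es): {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValidationError("class_proportions must be non-negative")
        if not set(self.probes_per_set_weights) <= {2, 3}:
            raise ValidationError("probes_per_set_weights keys must be in {2, 3}")
        if self.effect_size_log2 <= _MIN_FC_LOG2:
            raise ValidationError(
                f"effect_size_log2 must exceed log2(1.4) ≈ {_MIN_FC_LOG2:.4f} "
                "so planted effects are detectable by design"
            )
        if any(n < 2 for n in self.n_per_treatment.values()):
            raise DesignError(
                "every treatment needs >= 2 arrays (variance not estimable otherwise)"
            )
        if set(self.n_per_treatment) != set(TREATMENTS):
            raise ValidationError(
                f"n_per_treatment must cover exactly {list(TREATMENTS)}"
            )
        if self.n_probesets < 1:
            raise ValidationError("n_probesets must be positive")


def _draw_offsets(cls: str, rng: np.random.Generator, cfg: SimConfig) -> dict:
    """Per-treatment log2 offsets for one gene of the given class (AL = 0)."""
    e = cfg.effect_size_log2
    m = rng.uniform(e, e + 0.4)
    off = {t: 0.0 for t in TREATMENTS}
    if cls == "null":
        pass
    elif cls == "switching_up_in_fast":
        off["F2"], off["SK"] = -m, m
    elif cls == "switching_down_in_fast":
        off["F2"], off["SK"] = m, -m
    elif cls in ("chronic_up", "chronic_down"):
        s = 1.0 if cls == "chronic_up" else -1.0
        off["F2"] = off["SK"] = s * m
    elif cls == "chronic_and_switching_up":
        extra = rng.uniform(e, e + 0.4)
        off["F2"], off["SK"] = m, m + extra
    elif cls == "cr_responsive":
        # responds to the current energy state: offset in both the
        # chronically restricted and the fasting-day groups
        s = 1.0 if rng.random() < 0.5 else -1.0
        off["CR"] = off["SK"] = s * m
    else:  # pragma: no cover - guarded by SimConfig validation
        raise ValidationError(f"unknown class {cls!r}")
    return off


def simulate_dataset(config: SimConfig):
    """Generate one synthetic probe-level dataset.

    Returns
    -------
    probe_matrix : DataFrame
        probes × arrays log2 intensities (``attrs["log2"] = True``).
    probe_map : Series
        probe id → probe-set id.
    sample_sheet : DataFrame
        array id → treatment, individual id.
    truth : DataFrame
        per gene: generating ``pattern_class``, per-treatment offsets
        (``offset_AL`` .. ``offset_SK``, with ``offset_AL`` always 0) and
        ``true_variance`` drawn from the scaled inverse-chi-square prior.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"PS{i:05d}" for i in range(1, config.n_probesets + 1)]

    # sample sheet
    rows = []
    for t in TREATMENTS:
        for i in range(1, config.n_per_treatment[t] + 1):
            rows.append((f"{t}_{i}", t, f"bird_{t}_{i}"))
    sheet = pd.DataFrame(
        rows, columns=["array_id", "treatment", "individual_id"]
    ).set_index("array_id")
    arrays = sheet.index.to_numpy()
    treat_of_array = sheet["treatment"].to_numpy()

    # per-gene truth
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    gene_class = rng.choice(classes, size=config.n_probesets, p=probs / probs.sum())
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_probesets)
    d0, s0sq = config.var_prior_d0, config.var_prior_s0sq
    true_var = d0 * s0sq / rng.chisquare(d0, config.n_probesets)
    offsets = [_draw_offsets(c, rng, config) for c in gene_class]
    truth = pd.DataFrame(
        {
            "pattern_class": gene_class,
            **{
                f"offset_{t}": [o[t] for o in offsets] for t in TREATMENTS
            },
            "true_variance": true_var,
        },
        index=pd.Index(genes, name="gene"),
    )

    # gene-level expression: baseline + treatment offset + array-level noise
    offset_mat = np.stack(
        [truth[f"offset_{t}"].to_numpy() for t in TREATMENTS], axis=1
    )  # genes × 4
    t_index = np.array([TREATMENTS.index(t) for t in treat_of_array])
    signal = baselines[:, None] + offset_mat[:, t_index]
    noise = rng.normal(0.0, 1.0, signal.shape) * np.sqrt(true_var)[:, None]
    gene_expr = signal + noise
    if config.array_shift_sd > 0:
        gene_expr = gene_expr + rng.normal(0.0, config.array_shift_sd, len(arrays))

    # probe layer: 2-3 probes per set, each with a constant additive bias
    sizes = sorted(config.probes_per_set_weights)
    w = np.array([config.probes_per_set_weights[s] for s in sizes], dtype=float)
    n_probes = rng.choice(sizes, size=config.n_probesets, p=w / w.sum())
    probe_ids, probe_set_of, probe_rows = [], [], []
    for g in range(config.n_probesets):
        for p in range(1, int(n_probes[g]) + 1):
            probe_ids.append(f"{genes[g]}_p{p}")
            probe_set_of.append(genes[g])
            probe_rows.append(g)
    bias = rng.normal(0.0, config.probe_bias_sd, len(probe_ids))
    probe_values = gene_expr[np.array(probe_rows), :] + bias[:, None]
    probe_matrix = pd.DataFrame(
        probe_values, index=pd.Index(probe_ids, name="probe_id"), columns=arrays
    )
    probe_matrix.attrs["log2"] = True
    probe_map = pd.Series(
        probe_set_of, index=pd.Index(probe_ids, name="probe_id"), name="probeset_id"
    )
    return probe_matrix, probe_map, sheet, truth


@dataclass(frozen=True)
class TraitSimSpec:
    """A planted trait correlation: the named trait is generated so that its
    sample correlation with the target archetype score converges to
    ``planted_r`` as the number of individuals grows."""

    trait_name: str
    planted_r: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.trait_name not in TRAIT_NAMES:
            raise ValidationError(
                f"unknown trait {self.trait_name!r}; allowed: {list(TRAIT_NAMES)}"
            )
        if not -1.0 <= self.planted_r <= 1.0:
            raise ValidationError(f"|planted_r| must be <= 1, got {self.planted_r}")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


#: Plausible (mean, sd) unit scales for each trait in a five-week-old bird:
#: grams for masses, %BW for relative liver mass, mg and mg/g for lipid and
#: glycogen stores, arbitrary normalized units for ArcN gene expression.
_TRAIT_SCALES: dict[str, tuple[float, float]] = {
    "body_mass": (250.0, 25.0),
    "liver_mass": (7.0, 1.0),
    "relative_liver_mass": (2.8, 0.35),
    "total_liver_lipids": (350.0, 60.0),
    "liver_lipid_concentration": (50.0, 8.0),
    "total_liver_glycogen": (140.0, 35.0),
    "liver_glycogen_concentration": (20.0, 4.0),
    "AgRP": (1.0, 0.3),
    "POMC": (1.0, 0.3),
    "NPY": (1.0, 0.3),
}


def simulate_traits(
    archetype_scores: pd.Series, specs: list, seed: int
) -> pd.DataFrame:
    """Generate the ten-trait table with planted correlations.

    Each trait in ``specs`` is built as
    ``planted_r · z + sqrt(1 − r²) · ε`` with ``z`` the standardized archetype
    score and ``ε`` standard normal scaled by ``noise_sd`` jointly with the
    signal (an overall scale, so the correlation is unchanged); unspecified
    traits are independent noise.  All traits are then mapped to plausible
    units, and ``relative_liver_mass = 100 · liver_mass / body_mass`` is kept
    consistent by deriving whichever of the two liver variables was not a
    planted target from the other.
    """
    rng = np.random.default_rng(seed)
    idx = archetype_scores.index
    z = archetype_scores.to_numpy(dtype=float)
    sd = z.std()
    if sd == 0:
        raise ValidationError("archetype scores have zero variance")
    z = (z - z.mean()) / sd

    by_name = {}
    for spec in specs:
        if spec.trait_name in by_name:
            raise ValidationError(f"duplicate TraitSimSpec for {spec.trait_name!r}")
        by_name[spec.trait_name] = spec

    std_traits = {}
    for name in TRAIT_NAMES:
        eps = rng.normal(0.0, 1.0, len(idx))
        if name in by_name:
            r = by_name[name].planted_r
            std_traits[name] = by_name[name].noise_sd * (
                r * z + np.sqrt(1.0 - r * r) * eps
            )
        else:
            std_traits[name] = eps

    values = {}
    for name in TRAIT_NAMES:
        mean, scale = _TRAIT_SCALES[name]
        x = std_traits[name]
        x_sd = x.std()
        values[name] = mean + scale * (x / x_sd if x_sd > 0 else x)

    # keep relative_liver_mass = 100 * liver_mass / body_mass exactly
    if "relative_liver_mass" in by_name and "liver_mass" not in by_name:
        values["liver_mass"] = values["relative_liver_mass"] * values["body_mass"] / 100.0
    else:
        values["relative_liver_mass"] = 100.0 * values["liver_mass"] / values["body_mass"]

    return pd.DataFrame(values, index=pd.Index(idx, name="individual_id"))


def inject_outlier_arrays(
    probe_matrix: pd.DataFrame,
    array_ids: list,
    shift: float = 0.0,
    scramble: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Corrupt named arrays with a global intensity shift and, optionally, a
    within-array permutation of values (destroying inter-array correlation),
    to exercise the QC stage.  All other arrays are untouched."""
    unknown = [a for a in array_ids if a not in probe_matrix.columns]
    if unknown:
        raise ValidationError(f"unknown array id(s): {unknown}")
    rng = np.random.default_rng(seed)
    out = probe_matrix.copy()
    for a in array_ids:
        col = out[a].to_numpy().copy()
        if scramble:
            col = rng.permutation(col)
        out[a] = col + shift
    out.attrs.update(probe_matrix.attrs)
    return out


def planted_profile_groups(
    truth: pd.DataFrame, sample_sheet: pd.DataFrame, genes, k: int = 4
) -> pd.Series:
    """The planted k-way grouping of a gene subset.

    Builds each gene's noise-free expression profile across the arrays (its
    planted per-treatment offsets), standardizes rows, and applies the
    pipeline's default hierarchical clustering cut at ``k``.  This is the
    partition a perfect-recovery clustering of the noisy data would produce,
    and serves as the oracle for cluster-recovery tests.
    """
    from .clustering import cluster_genes, cut_k, standardize_rows

    genes = list(genes)
    t_of = sample_sheet["treatment"]
    profiles = pd.DataFrame(
        {
            a: truth.loc[genes, f"offset_{t_of[a]}"].to_numpy()
            for a in sample_sheet.index
        },
        index=pd.Index(genes, name="gene"),
    )
    nonconst = profiles.std(axis=1) > 0
    std = standardize_rows(profiles.loc[nonconst])
    dend = cluster_genes(std)
    groups = cut_k(dend, k)
    # constant-profile (null) genes, if any, get group 0
    return groups.reindex(genes, fill_value=0)


#: The 4-way grouping of the switching/chronic classes by profile archetype:
#: the two switching directions are their own groups and the chronic classes
#: group by direction (chronic_and_switching_up shares the chronic-up
#: profile, with a steeper fasting-day offset).
CLASS_GROUPS_4WAY: dict[str, int] = {
    "switching_up_in_fast": 1,
    "switching_down_in_fast": 2,
    "chronic_up": 3,
    "chronic_and_switching_up": 3,
    "chronic_down": 4,
}


def planted_class_groups(truth: pd.DataFrame, genes) -> pd.Series:
    """The planted 4-way grouping of the switching/chronic genes in ``genes``.

    Genes of other classes (null, restriction-responsive) are dropped: the
    co-clustering oracle is about whether the switching and chronic classes
    land in distinct clusters, wherever the remaining genes fall.
    """
    classes = truth.loc[list(genes), "pattern_class"]
    keep = classes.isin(CLASS_GROUPS_4WAY)
    return classes[keep].map(CLASS_GROUPS_4WAY).rename("group")


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", float_format="%.10g")


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def default_config(**overrides) -> SimConfig:
    """A :class:`SimConfig` with study-design defaults, overridable by field."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()
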