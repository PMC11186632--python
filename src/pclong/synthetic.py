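"""Synthetic data with known ground truth for every analysis stage.

Four generators emulate the statistical structure the downstream analyses
assume:

* spatial point patterns of two plasma-cell subsets ("bulk", "llpc") placed
  either uniformly (complete spatial randomness, CSR) or by a Thomas-like
  parent-offspring cluster process with a tunable offspring scatter;
* cell tracks as isotropic Gaussian random walks with two motility
  phenotypes (sessile vs motile) plus per-frame arrest, and two fluorescence
  channels separating the phenotypes by intensity ratio;
* timestamped-cohort decay series following the one-phase model with
  mean-corrected multiplicative lognormal noise;
* BCR repertoires with Zipf (power-law) clone abundances, cross-mouse
  "public" clones spiked by construction, subset-specific isotype mixtures
  and subset-specific Poisson mutation loads, emitted as AIRR-style
  rearrangement rows.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import DecaySeries
from .spatial import PointPattern
from .tracks import Track

__all__ = [
    "SpatialSimConfig",
    "TrackSimConfig",
    "DecaySimConfig",
    "RepertoireSimConfig",
    "gen_point_pattern",
    "gen_tracks",
    "gen_decay_cohort",
    "gen_repertoire",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_DEFAULT_V_GENES = (
    "IGHV1-26", "IGHV1-53", "IGHV2-2", "IGHV3-6", "IGHV5-17",
    "IGHV8-9", "IGHV9-3", "IGHV14-3",
)
_ISOTYPE_ORDER = ("IgM", "IgG", "IgA")


# ---------------------------------------------------------------- spatial

@dataclass
class SpatialSimConfig:
    """Two-subset point pattern in a box; CSR or parent-offspring clustered.

    ``llpc_cluster_affinity`` is the probability that an LLPC is placed as
    clustered offspring rather than uniformly; in clustered mode bulk cells
    are always offspring. Offspring scatter is isotropic Gaussian with sd
    ``offspring_sd`` micrometres; offspring landing outside the box are
    resampled, not clipped, to avoid boundary density artifacts.
    """

    box_extent: tuple[float, ...] = (500.0, 500.0, 500.0)
    n_cells_per_subset: tuple[int, int] = (500, 150)  # (bulk, llpc)
    process: str = "csr"                               # "csr" | "clustered"
    n_parents: int = 10
    offspring_sd: float = 10.0
    llpc_cluster_affinity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.box_extent):
            raise ValueError("box extent must be positive on every axis")
        if len(self.box_extent) not in (2, 3):
            raise ValueError("box must be 2D or 3D")
        if not 0 <= self.llpc_cluster_affinity <= 1:
            raise ValueError("llpc_cluster_affinity must lie in [0, 1]")
        if self.process not in ("csr", "clustered"):
            raise ValueError(f"unknown process {self.process!r}")
        if min(self.n_cells_per_subset) < 0:
            raise ValueError("cell counts must be non-negative")


def _offspring(rng, parents, n, sd, extent):
    """n offspring around random parents, resampled until inside the box."""
    extent = np.asarray(extent)
    out = np.empty((n, extent.size))
    for i in range(n):
        while True:
            p = parents[rng.integers(parents.shape[0])]
            pos = p + rng.normal(0.0, sd, size=extent.size)
            if (pos >= 0).all() and (pos <= extent).all():
                out[i] = pos
                break
    return out


def gen_point_pattern(config: SpatialSimConfig) -> tuple[PointPattern, dict]:
    """Generate a labeled point pattern and its ground truth.

    Returns the pattern and a dict with the cluster parent locations (empty
    under CSR) for oracle testing.
    """
    rng = np.random.default_rng(config.seed)
    extent = np.asarray(config.box_extent)
    d = extent.size
    n_bulk, n_llpc = config.n_cells_per_subset

    truth: dict = {"process": config.process, "parents": np.empty((0, d))}
    if config.process == "csr":
        bulk = rng.uniform(0, extent, size=(n_bulk, d))
        llpc = rng.uniform(0, extent, size=(n_llpc, d))
    else:
        parents = rng.uniform(0, extent, size=(config.n_parents, d))
        truth["parents"] = parents
        bulk = _offspring(rng, parents, n_bulk, config.offspring_sd, extent)
        clustered_flags = rng.random(n_llpc) < config.llpc_cluster_affinity
        llpc = np.empty((n_llpc, d))
        n_clu = int(clustered_flags.sum())
        if n_clu:
            llpc[clustered_flags] = _offspring(
                rng, parents, n_clu, config.offspring_sd, extent
            )
        if n_llpc - n_clu:
            llpc[~clustered_flags] = rng.uniform(
                0, extent, size=(n_llpc - n_clu, d)
            )
        truth["llpc_clustered"] = clustered_flags
    positions = np.vstack([bulk, llpc]) if n_bulk + n_llpc else np.empty((0, d))
    labels = np.array(["bulk"] * n_bulk + ["llpc"] * n_llpc)
    return PointPattern(positions, labels, tuple(extent)), truth


# ----------------------------------------------------------------- tracks

@dataclass
class TrackSimConfig:
    """Gaussian random-walk tracks for two motility phenotypes.

    Each frame a cell either arrests (probability ``arrest_prob``) or takes
    an isotropic Gaussian step with per-axis sd ``step_sd`` micrometres.
    Channel intensities are drawn per frame around the phenotype's
    ``channel_means`` (yfp, tomato) with sd ``channel_sd``. Frames are
    ``frame_interval`` minutes apart (default 3, the standard time-lapse
    cadence).
    """

    n_tracks: dict[str, int] = field(
        default_factory=lambda: {"sessile": 100, "motile": 100}
    )
    frame_interval: float = 3.0
    n_frames: int = 20
    dims: int = 3
    step_sd: dict[str, float] = field(
        default_factory=lambda: {"sessile": 0.2, "motile": 2.0}
    )
    arrest_prob: dict[str, float] = field(
        default_factory=lambda: {"sessile": 0.5, "motile": 0.0}
    )
    channel_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"sessile": (80.0, 100.0), "motile": (120.0, 100.0)}
    )
    channel_sd: float = 1.0
    box_extent: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for ph, sd in self.step_sd.items():
            if sd < 0:
                raise ValueError(f"step_sd[{ph!r}] must be >= 0")
        for ph, p in self.arrest_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"arrest_prob[{ph!r}] must lie in [0, 1]")


def gen_tracks(config: TrackSimConfig) -> list[Track]:
    """Simulate phenotype-labeled random-walk tracks.

    Ground-truth phenotype is stored in each track's metadata under
    ``"phenotype"``; start positions are uniform in ``box_extent`` when
    given, else at the origin.
    """
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_frames) * config.frame_interval
    out: list[Track] = []
    for phenotype in sorted(config.n_tracks):
        n = config.n_tracks[phenotype]
        sd = config.step_sd[phenotype]
        arrest = config.arrest_prob[phenotype]
        yfp_mu, tom_mu = config.channel_means[phenotype]
        for i in range(n):
            steps = rng.normal(0.0, sd, size=(config.n_frames - 1, config.dims))
            moving = rng.random(config.n_frames - 1) >= arrest
            steps *= moving[:, None]
            if config.box_extent is not None:
                start = rng.uniform(0, np.asarray(config.box_extent))
            else:
                start = np.zeros(config.dims)
            pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
            yfp = np.maximum(rng.normal(yfp_mu, config.channel_sd, config.n_frames), 1e-6)
            tom = np.maximum(rng.normal(tom_mu, config.channel_sd, config.n_frames), 1e-6)
            out.append(
                Track(
                    track_id=f"{phenotype}_{i:05d}",
                    t=t,
                    positions=pos,
                    ch_yfp=yfp,
                    ch_tomato=tom,
                    metadata={"phenotype": phenotype},
                )
            )
    return out


# ------------------------------------------------------------------ decay

@dataclass
class DecaySimConfig:
    """Replicated one-phase decay cohorts with multiplicative noise.

    Counts follow ``(n0 - plateau) * 2^(-t / t_half) + plateau``; each
    observation is multiplied by mean-1 lognormal noise with coefficient of
    variation ``noise_cv`` (0 reproduces the exact exponential). Default
    timepoints match a days 5/30/90/150 timestamping design.
    """

    n0: float = 1000.0
    t_half: float = 60.0
    plateau: float = 0.0
    timepoints: tuple[float, ...] = (5.0, 30.0, 90.0, 150.0)
    noise_cv: float = 0.2
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be positive")
        tp = np.asarray(self.timepoints)
        if tp.size == 0 or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def gen_decay_cohort(config: DecaySimConfig) -> DecaySeries:
    """Noisy replicated counts along an exponential decay.

    The lognormal multiplier uses sigma^2 = ln(1 + cv^2) with a -sigma^2/2
    mean correction so replicate means stay unbiased around the noiseless
    curve.
    """
    rng = np.random.default_rng(config.seed)
    tp = np.asarray(config.timepoints, dtype=float)
    clean = (config.n0 - config.plateau) * np.power(2.0, -tp / config.t_half) + config.plateau
    t_all, y_all, rep_all = [], [], []
    for rep in range(config.n_replicates):
        if config.noise_cv > 0:
            sigma2 = np.log1p(config.noise_cv**2)
            mult = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=tp.size))
        else:
            mult = np.ones(tp.size)
        t_all.append(tp)
        y_all.append(clean * mult)
        rep_all.append(np.full(tp.size, rep))
    return DecaySeries(
        timepoints=np.concatenate(t_all),
        counts=np.concatenate(y_all),
        replicate_ids=np.concatenate(rep_all),
        metadata={"t_half_true": config.t_half, "n0_true": config.n0},
    )


# ------------------------------------------------------------- repertoire

@dataclass
class RepertoireSimConfig:
    """Multi-mouse BCR repertoires with spiked public clones.

    Clone abundances follow a Zipf law (rank^-s weights) multinomially
    sampled over ``reads_per_sample`` reads, which yields heavy-tailed clone
    sizes including the singletons/doubletons richness estimators need.
    ``n_public_clones`` keys are spiked into >=2 samples from different mice
    (LLPC-labeled samples preferred with probability ``public_llpc_bias``)
    with duplicate counts of at least 10 so they survive the default size
    filter; every private CDR3 is globally unique by construction so the
    spike-in list is the exact ground truth for public-clone detection.
    ``mutation_mean`` gives the Poisson mean V-region mutation count per
    subset.
    """

    n_mice: int = 4
    samples_per_mouse: tuple[tuple[str, str], ...] = (
        ("BM", "llpc"), ("BM", "bulk"), ("spleen", "llpc"), ("spleen", "bulk"),
    )
    n_clones_per_sample: int = 300
    zipf_exponent: float = 1.2
    reads_per_sample: int = 6000
    n_public_clones: int = 25
    public_llpc_bias: float = 0.75
    isotype_probs: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=lambda: {
            ("BM", "llpc"): (0.05, 0.45, 0.50),
            ("BM", "bulk"): (0.30, 0.50, 0.20),
            ("spleen", "llpc"): (0.10, 0.60, 0.30),
            ("spleen", "bulk"): (0.40, 0.45, 0.15),
        }
    )
    mutation_mean: dict[str, float] = field(
        default_factory=lambda: {"llpc": 2.0, "bulk": 6.0}
    )
    v_genes: tuple[str, ...] = _DEFAULT_V_GENES
    v_length: int = 300
    timepoint_day: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        for grp, probs in self.isotype_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"isotype probs for {grp} do not sum to 1")
        if self.n_mice < 1:
            raise ValueError("need at least one mouse")
        if self.n_public_clones > 0 and self.n_mice < 2:
            raise ValueError("public clones need >=2 mice")


def _random_cdr3(rng, used: set[str]) -> str:
    while True:
        length = int(rng.integers(8, 21))
        s = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))
        if s not in used:
            used.add(s)
            return s


def gen_repertoire(
    config: RepertoireSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Generate rearrangement rows, sample metadata, and the public-clone truth.

    Returns
    -------
    (rearrangements, metadata, public_keys)
        ``rearrangements`` is an AIRR-style table (sequence_id, sample_id,
        locus, v_call, c_call, junction_aa, duplicate_count, mutation_count,
        v_sequence_length); ``metadata`` has one row per sample (sample_id,
        mouse_id, tissue, subset, timepoint_day, age_group); ``public_keys``
        is the spiked list of (V gene, CDR3 aa) keys.
    """
    rng = np.random.default_rng(config.seed)
    used_cdr3: set[str] = set()
    v_genes = list(config.v_genes)

    meta_rows = []
    samples: list[dict] = []
    for m in range(config.n_mice):
        mouse_id = f"mouse{m + 1}"
        age = "young" if m < (config.n_mice + 1) // 2 else "middle-aged"
        for tissue, subset in config.samples_per_mouse:
            sid = f"{mouse_id}_{tissue}_{subset}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "mouse_id": mouse_id,
                    "tissue": tissue,
                    "subset": subset,
                    "timepoint_day": config.timepoint_day,
                    "age_group": age,
                }
            )
            samples.append({"sample_id": sid, "mouse_id": mouse_id,
                            "tissue": tissue, "subset": subset})

    # spiked public clones: each into >=2 samples from >=2 distinct mice
    public_keys: list[tuple[str, str]] = []
    public_assign: dict[str, list[tuple[str, str]]] = {s["sample_id"]: [] for s in samples}
    llpc_by_mouse: dict[str, list[dict]] = {}
    all_by_mouse: dict[str, list[dict]] = {}
    for s in samples:
        all_by_mouse.setdefault(s["mouse_id"], []).append(s)
        if s["subset"] == "llpc":
            llpc_by_mouse.setdefault(s["mouse_id"], []).append(s)
    mice = sorted(all_by_mouse)
    for _ in range(config.n_public_clones):
        v = v_genes[rng.integers(len(v_genes))]
        cdr3 = _random_cdr3(rng, used_cdr3)
        key = (v, cdr3)
        public_keys.append(key)
        n_host_mice = int(rng.integers(2, config.n_mice + 1))
        host_mice = rng.choice(mice, size=n_host_mice, replace=False)
        for mouse in host_mice:
            prefer_llpc = rng.random() < config.public_llpc_bias
            pool = llpc_by_mouse.get(mouse) if prefer_llpc else None
            if not pool:
                pool = all_by_mouse[mouse]
            s = pool[rng.integers(len(pool))]
            public_assign[s["sample_id"]].append(key)

    rows = []
    seq_counter = 0
    for s in samples:
        tissue, subset = s["tissue"], s["subset"]
        iso_p = np.asarray(config.isotype_probs[(tissue, subset)])
        mut_mu = config.mutation_mean[subset]

        # private clones: Zipf-weighted multinomial read allocation
        n_clones = config.n_clones_per_sample
        ranks = np.arange(1, n_clones + 1, dtype=float)
        w = ranks ** (-config.zipf_exponent)
        sizes = rng.multinomial(config.reads_per_sample, w / w.sum())
        clone_keys = [
            (v_genes[rng.integers(len(v_genes))], _random_cdr3(rng, used_cdr3))
            for _ in range(n_clones)
        ]
        spiked = [(k, int(rng.integers(10, 51))) for k in public_assign[s["sample_id"]]]
        for (v, cdr3), size in list(zip(clone_keys, sizes)) + spiked:
            if size == 0:
                continue  # unobserved clone: no sequencing reads sampled
            allele = f"{v}*{int(rng.integers(1, 4)):02d}"
            isotype = _ISOTYPE_ORDER[rng.choice(3, p=iso_p)]
            c_call = {"IgM": "IGHM", "IgG": "IGHG1", "IgA": "IGHA"}[isotype]
            mut = int(rng.poisson(mut_mu))
            rows.append(
                {
                    "sequence_id": f"seq{seq_counter:07d}",
                    "sample_id": s["sample_id"],
                    "locus": "IGH",
                    "v_call": allele,
                    "c_call": c_call,
                    "junction_aa": cdr3,
                    "duplicate_count": int(size),
                    "mutation_count": min(mut, config.v_length),
                    "v_sequence_length": config.v_length,
                }
            )
            seq_counter += 1
    return pd.DataFrame(rows), pd.DataFrame(meta_rows), public_keys
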