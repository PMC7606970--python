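"""Synthetic study generator for the nested halite sampling design.

Emulates the data the spatial analysis consumes, with known ground truth:

* a nested sampling design — regions ≫ hill sites ≫ nodules ≫ vertical
  slices ≫ top/middle/bottom positions — mirroring the field survey
  (2 regions ~20 km apart, 2 hill sites ~300 m apart, 6 nodules within
  ~10 m, 3 slices per nodule, 3 vertical positions per slice);
* ASV count tables from a logistic-normal model: per-sample log-abundances
  are a taxon baseline plus humidity and light effects plus independent
  Gaussian drift at every nesting level, passed through a softmax and
  sampled multinomially at a fixed read depth;
* diel relative-humidity/temperature cycles with injected dew (RH > 95 %)
  and fog (RH > 99 %) events;
* Beer–Lambert attenuated transmission spectra, intensity(λ, d) =
  source(λ)·exp(−k(λ)·d);
* Poisson-distributed microscope field counts around the expectation implied
  by a true cell density.

Covariates are derived from the design: the light index is −depth (log-PAR
declines linearly with depth under Beer–Lambert attenuation) and the
humidity index is a Gaussian bump peaking at 2.5 cm below the surface (the
nodule interior buffers humidity; the periphery dries out), plus optional
per-region offsets.  Every generator takes an explicit seed and is
bit-reproducible; no global random state is touched.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biomass import CountingConstants, FieldCountSet
from .env_sensors import Event, SensorSeries
from .light_par import Spectrum

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "GroundTruth",
    "DRIFT_LEVELS",
    "POSITION_DEPTH_BANDS_CM",
    "generate_metadata",
    "generate_counts",
    "generate_sensor_series",
    "generate_spectra",
    "generate_tree",
    "generate_field_counts",
    "rh_index",
    "light_index",
]

#: Nesting levels at which independent Gaussian drift is drawn, coarsest
#: first.  ``position`` is the per-(nodule, vertical position) effect that
#: makes horizontal neighbours (same position, different slice) more alike
#: than vertical neighbours, as observed in the field.
DRIFT_LEVELS = ("region", "site", "nodule", "position", "slice", "residual")

#: Depth bands (cm below the nearest surface) per vertical position; the
#: middle band matches the observed interior abundance peak at 2–3 cm.
POSITION_DEPTH_BANDS_CM = {
    "top": (0.5, 1.5),
    "bottom": (0.5, 1.5),
    "middle": (2.0, 4.0),
}


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the nested sampling design."""

    n_regions: int = 2
    sites_per_region: int = 2
    nodules_per_site: int = 6
    slices_per_nodule: int = 3
    positions: tuple[str, ...] = ("top", "middle", "bottom")
    reads_per_sample: int = 5000
    n_taxa: int = 40

    def __post_init__(self) -> None:
        for name in ("n_regions", "sites_per_region", "nodules_per_site",
                     "slices_per_nodule", "n_taxa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.positions:
            raise ValueError("positions must be non-empty")
        if self.reads_per_sample < 100:
            raise ValueError("reads_per_sample must be >= 100")

    @property
    def n_samples(self) -> int:
        return (self.n_regions * self.sites_per_region * self.nodules_per_site
                * self.slices_per_nodule * len(self.positions))

    @classmethod
    def from_json(cls, path) -> "DesignSpec":
        with open(path) as fh:
            d = json.load(fh)
        if "positions" in d:
            d["positions"] = tuple(d["positions"])
        return cls(**d)


@dataclass
class EffectSpec:
    """Taxon-level environmental effects and nested drift magnitudes.

    ``beta_rh`` and ``beta_light`` are per-taxon log-abundance slopes
    against the humidity index (unitless, 0–1 scale) and light index
    (log-PAR scale, −depth in cm).  ``drift_sd`` maps each nesting level in
    :data:`DRIFT_LEVELS` to the SD of its iid Gaussian per-taxon effect.
    """

    beta_rh: np.ndarray
    beta_light: np.ndarray
    baseline: np.ndarray
    drift_sd: dict[str, float]

    def __post_init__(self) -> None:
        self.beta_rh = np.asarray(self.beta_rh, dtype=float)
        self.beta_light = np.asarray(self.beta_light, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        n = len(self.baseline)
        if len(self.beta_rh) != n or len(self.beta_light) != n:
            raise ValueError("coefficient vectors must share length n_taxa")
        unknown = set(self.drift_sd) - set(DRIFT_LEVELS)
        if unknown:
            raise ValueError(f"unknown drift levels: {sorted(unknown)}")
        for k, v in self.drift_sd.items():
            if v < 0:
                raise ValueError(f"drift SD for {k} must be >= 0")
        self.drift_sd = {k: float(self.drift_sd.get(k, 0.0)) for k in DRIFT_LEVELS}

    @property
    def n_taxa(self) -> int:
        return len(self.baseline)

    @classmethod
    def null(cls, n_taxa: int) -> "EffectSpec":
        """No environmental effects, no drift: exchangeable samples."""
        z = np.zeros(n_taxa)
        return cls(beta_rh=z, beta_light=z.copy(), baseline=z.copy(),
                   drift_sd={})

    @classmethod
    def nested_drift(
        cls,
        n_taxa: int,
        region: float = 0.8,
        site: float = 0.5,
        nodule: float = 0.3,
        position: float = 0.2,
        slice: float = 0.12,
        residual: float = 0.05,
    ) -> "EffectSpec":
        """Pure ecological drift with SDs shrinking toward finer levels,
        producing distance decay of community similarity."""
        z = np.zeros(n_taxa)
        return cls(
            beta_rh=z, beta_light=z.copy(), baseline=z.copy(),
            drift_sd=dict(region=region, site=site, nodule=nodule,
                          position=position, slice=slice, residual=residual),
        )

    @classmethod
    def intra_nodule_gradient(cls, n_taxa: int = 40) -> "EffectSpec":
        """Taxa with the field survey's intra-nodule structure.

        Taxon 0 is a phototroph whose light slope yields ~+80 % relative
        enrichment at the top (mean depth 1 cm) versus the middle (mean
        depth 3 cm); taxa 1–3 are humidity-dependent heterotrophs whose
        slopes against the interior-peaked humidity index yield roughly
        +310 %, +70 % and +50 % middle-versus-surface enrichment.  Drift is
        confined to the levels present within one site.
        """
        if n_taxa < 5:
            raise ValueError("gradient preset needs at least 5 taxa")
        beta_rh = np.zeros(n_taxa)
        beta_light = np.zeros(n_taxa)
        baseline = np.zeros(n_taxa)
        # dominant background community (salt-in specialists)
        baseline[4:] = 2.0
        d_top, d_mid = 1.0, 3.0
        # calibrated so the *realized* mean relative-abundance ratio of the
        # phototroph between the top and middle depth bands is 1.8 after
        # softmax normalization (the interior taxa inflate the middle-sample
        # denominator, so the slope is below log(1.8)/2)
        beta_light[0] = 0.24073
        drh = rh_index(d_mid) - rh_index(d_top)
        beta_rh[1] = np.log(4.1) / drh
        beta_rh[2] = np.log(1.7) / drh
        beta_rh[3] = np.log(1.5) / drh
        return cls(
            beta_rh=beta_rh, beta_light=beta_light, baseline=baseline,
            drift_sd=dict(nodule=0.15, position=0.1, slice=0.1, residual=0.15),
        )


@dataclass
class GroundTruth:
    """Generating parameters and realized latent quantities, for
    parameter-recovery tests."""

    covariates: pd.DataFrame | None = None
    random_effects: dict | None = None
    events: list | None = None
    true_density: float | None = None
    expected_cells_per_field: float | None = None
    attenuation_k: np.ndarray | None = None


def rh_index(depth_cm) -> np.ndarray:
    """Humidity index (0–1) versus depth: Gaussian bump peaking at 2.5 cm
    (SD 1.5 cm) — the interior buffers humidity, the periphery dries."""
    d = np.asarray(depth_cm, dtype=float)
    return np.exp(-((d - 2.5) ** 2) / (2 * 1.5**2))


def light_index(depth_cm) -> np.ndarray:
    """Light index: log-PAR declines linearly with depth under Beer–Lambert
    attenuation; unit attenuation per cm."""
    return -np.asarray(depth_cm, dtype=float)


def generate_metadata(design: DesignSpec, seed: int) -> pd.DataFrame:
    """One sample per (region, site, nodule, slice, position).

    Identifiers are hierarchical (a nodule id embeds its site and region),
    so equality comparisons respect the nesting.  Depth below the nearest
    surface is drawn uniformly within the position's band
    (:data:`POSITION_DEPTH_BANDS_CM`; unlisted labels use the surface band).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r, s, nd, sl, pos in itertools.product(
        range(design.n_regions), range(design.sites_per_region),
        range(design.nodules_per_site), range(design.slices_per_nodule),
        design.positions,
    ):
        region = f"R{r}"
        site = f"{region}-S{s}"
        nodule = f"{site}-N{nd}"
        slice_id = f"{nodule}-L{sl}"
        lo, hi = POSITION_DEPTH_BANDS_CM.get(pos, (0.5, 1.5))
        rows.append({
            "sample_id": f"{slice_id}-{pos}",
            "region": region, "site": site, "nodule": nodule,
            "slice": slice_id, "position": pos,
            "distance_cm": rng.uniform(lo, hi),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_counts(
    metadata: pd.DataFrame,
    effects: EffectSpec,
    design: DesignSpec,
    seed: int,
    rh_region_offset: dict | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample an ASV count table under the logistic-normal model.

    Per-sample log-abundance is
    η_is = baseline_i + β_rh,i·RH_s + β_light,i·L_s + Σ_levels drift, with
    counts drawn multinomially from softmax(η) at the design read depth.
    ``rh_region_offset`` optionally shifts the humidity index per region
    (e.g. a more humid southern region).
    """
    if len(metadata) != design.n_samples:
        raise ValueError(
            f"metadata has {len(metadata)} rows but the design implies "
            f"{design.n_samples} samples"
        )
    if effects.n_taxa != design.n_taxa:
        raise ValueError(
            f"effects cover {effects.n_taxa} taxa but the design has "
            f"{design.n_taxa}"
        )
    unknown_pos = set(metadata["position"]) - set(design.positions)
    if unknown_pos:
        raise ValueError(f"metadata positions not in design: {sorted(unknown_pos)}")

    rng = np.random.default_rng(seed)
    m = design.n_taxa
    rh = rh_index(metadata["distance_cm"].to_numpy())
    if rh_region_offset:
        rh = rh + metadata["region"].map(rh_region_offset).fillna(0.0).to_numpy()
    light = light_index(metadata["distance_cm"].to_numpy())

    level_cols = {"region": metadata["region"], "site": metadata["site"],
                  "nodule": metadata["nodule"],
                  "position": metadata["nodule"].astype(str) + ":" +
                              metadata["position"].astype(str),
                  "slice": metadata["slice"],
                  "residual": pd.Series(metadata.index, index=metadata.index)}
    eta = (effects.baseline[None, :]
           + np.outer(rh, effects.beta_rh)
           + np.outer(light, effects.beta_light))
    random_effects: dict[str, dict] = {}
    for level in DRIFT_LEVELS:
        sd = effects.drift_sd[level]
        groups = level_cols[level]
        uniq = pd.unique(groups)
        draws = {g: rng.normal(0.0, sd, size=m) if sd > 0 else np.zeros(m)
                 for g in uniq}
        random_effects[level] = draws
        eta += np.stack([draws[g] for g in groups])

    probs = np.exp(eta - eta.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.stack([
        rng.multinomial(design.reads_per_sample, p) for p in probs
    ])
    table = pd.DataFrame(
        counts, index=metadata.index,
        columns=[f"ASV{i:04d}" for i in range(m)],
    )
    truth = GroundTruth(
        covariates=pd.DataFrame({"rh_index": rh, "light_index": light},
                                index=metadata.index),
        random_effects=random_effects,
    )
    return table, truth


def generate_sensor_series(
    n_days: int,
    site_offset_t: float = 0.0,
    site_offset_rh: float = 0.0,
    events: list[tuple] = (),
    seed: int = 0,
    start: str = "2019-03-25",
    t_mean: float = 18.0,
    t_amp: float = 8.0,
    rh_mean: float = 55.0,
    rh_amp: float = 25.0,
    noise_sd: float = 1.5,
    label: str = "",
) -> tuple[SensorSeries, GroundTruth]:
    """Diel RH/temperature series at 30-min cadence with injected events.

    Baseline: sinusoids peaking at 14:00 (temperature) and 04:00 (RH) plus
    site offsets and Gaussian noise; defaults keep baseline RH below the
    dew threshold.  Each event is ``(kind, day, start_hour, duration_h)``
    with kind 'dew' or 'fog'; over its span RH is forced into (95, 98] for
    dew or (99, 99.8] for fog.  Overlapping events of the same kind are
    rejected.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    n = 48 * n_days
    time = pd.date_range(start=start, periods=n, freq="30min")
    hours = time.hour.to_numpy() + time.minute.to_numpy() / 60.0
    temp = (t_mean + site_offset_t
            + t_amp * np.cos(2 * np.pi * (hours - 14) / 24)
            + rng.normal(0, noise_sd, n))
    rh = (rh_mean + site_offset_rh
          + rh_amp * np.cos(2 * np.pi * (hours - 4) / 24)
          + rng.normal(0, noise_sd, n))
    rh = np.clip(rh, 0.0, 100.0)

    spans: dict[str, list[tuple[float, float]]] = {"dew": [], "fog": []}
    truth_events: list[Event] = []
    for kind, day, start_hour, duration_h in events:
        if kind not in ("dew", "fog"):
            raise ValueError(f"unknown event kind {kind!r}")
        if duration_h <= 0:
            raise ValueError("event duration must be positive")
        t0 = day * 24.0 + start_hour
        t1 = t0 + duration_h
        if t0 < 0 or t1 > n_days * 24.0:
            raise ValueError("event extends outside the series span")
        for a, b in spans[kind]:
            if t0 < b and a < t1:
                raise ValueError(f"overlapping injected {kind} events")
        spans[kind].append((t0, t1))
        abs_hours = np.arange(n) * 0.5
        mask = (abs_hours >= t0) & (abs_hours < t1)
        if kind == "dew":
            rh[mask] = 95.5 + 2.0 * rng.random(mask.sum())
        else:
            rh[mask] = 99.1 + 0.7 * rng.random(mask.sum())
        truth_events.append(Event(
            kind=kind,
            start=time[0] + pd.Timedelta(hours=t0),
            end=time[0] + pd.Timedelta(hours=t1),
            duration_h=float(duration_h),
            n_samples=int(mask.sum()),
        ))
    series = SensorSeries(time=time, rh=rh, temp=temp, label=label)
    return series, GroundTruth(events=truth_events)


def generate_spectra(
    depths, k, source: Spectrum
) -> list[Spectrum]:
    """Beer–Lambert attenuated spectra: intensity(λ, d) = source(λ)·e^(−k(λ)·d).

    ``k`` is the attenuation coefficient per cm on the source's wavelength
    grid; depth 0 returns the source spectrum.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != source.wavelength_nm.shape:
        raise ValueError(
            "attenuation grid does not match the source wavelength grid "
            f"({k.shape} vs {source.wavelength_nm.shape})"
        )
    if (k <= 0).any():
        raise ValueError("attenuation coefficients must be positive")
    out = []
    for d in depths:
        if d < 0:
            raise ValueError("depths must be non-negative")
        out.append(Spectrum(
            wavelength_nm=source.wavelength_nm.copy(),
            intensity=source.intensity * np.exp(-k * d),
        ))
    return out


def generate_tree(n_taxa: int, seed: int, taxa: list[str] | None = None) -> str:
    """Random rooted bifurcating tree over ``n_taxa`` tips as a Newick
    string; branch lengths are exponential with a small floor."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    if taxa is None:
        taxa = [f"ASV{i:04d}" for i in range(n_taxa)]
    if len(taxa) != n_taxa:
        raise ValueError("taxa list must have n_taxa entries")

    def build(labels: list[str]) -> str:
        length = 0.05 + rng.exponential(0.3)
        if len(labels) == 1:
            return f"{labels[0]}:{length:.6f}"
        split = int(rng.integers(1, len(labels)))
        left, right = build(labels[:split]), build(labels[split:])
        return f"({left},{right}):{length:.6f}"

    if n_taxa == 1:
        return f"({taxa[0]}:{0.05 + rng.exponential(0.3):.6f});"
    split = int(rng.integers(1, n_taxa))
    return f"({build(list(taxa[:split]))},{build(list(taxa[split:]))});"


def generate_field_counts(
    true_density: float,
    constants: CountingConstants,
    n_images: int,
    seed: int,
    sample: str = "",
) -> tuple[FieldCountSet, GroundTruth]:
    """Poisson per-image counts around the expectation implied by a true
    cell density (cells/g) and the counting constants.

    The inverse density estimator applied to the noiseless expectation
    recovers ``true_density`` exactly.
    """
    if true_density <= 0:
        raise ValueError("true_density must be positive")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    expected = true_density / constants.cells_per_count
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected, size=n_images)
    fields = FieldCountSet(counts=counts, sample=sample)
    return fields, GroundTruth(
        true_density=float(true_density),
        expected_cells_per_field=float(expected),
    )


def write_simulation(
    out_dir,
    design: DesignSpec,
    effects: EffectSpec,
    seed: int,
) -> dict:
    """Generate and write a full synthetic study to ``out_dir``.

    Writes counts.tsv, metadata.tsv, tree.nwk, sensors_{north,south}.csv,
    spectra CSVs at three depths, and ground_truth.json; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    meta = generate_metadata(design, seed=int(rng.integers(2**31)))
    table, truth = generate_counts(meta, effects, design,
                                   seed=int(rng.integers(2**31)))
    newick = generate_tree(design.n_taxa, seed=int(rng.integers(2**31)))

    north, _ = generate_sensor_series(
        30, events=[("dew", d, 2.0, 3.0) for d in range(0, 30, 5)],
        seed=int(rng.integers(2**31)), label="north")
    south, _ = generate_sensor_series(
        30, site_offset_t=-5.2, site_offset_rh=11.0,
        events=[("fog", d, 3.0, 6.0) for d in range(0, 30, 7)],
        seed=int(rng.integers(2**31)), label="south")

    wl = np.linspace(400, 900, 251)
    lamp = Spectrum(wl, 1000.0 * np.exp(-((wl - 650) ** 2) / (2 * 180.0**2)))
    kcoef = 1.5 + 1.5 * np.exp(-((wl - 680) ** 2) / (2 * 60.0**2))
    spectra = generate_spectra([0.0, 1.0, 3.0], kcoef, lamp)

    paths = {}
    table.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "metadata.tsv", sep="\t")
    (out / "tree.nwk").write_text(newick + "\n")
    north.to_csv(out / "sensors_north.csv")
    south.to_csv(out / "sensors_south.csv")
    for spec, name in zip(spectra, ["lamp", "depth1cm", "depth3cm"]):
        spec.to_csv(out / f"spectrum_{name}.csv")
    (out / "ground_truth.json").write_text(json.dumps({
        "seed": seed,
        "design": asdict(design),
        "drift_sd": effects.drift_sd,
    }, default=list, indent=2))
    for p in out.iterdir():
        paths[p.name] = str(p)
    return paths
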