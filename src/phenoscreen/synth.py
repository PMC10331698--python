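"""Synthetic screen generation with known ground truth.

The generator emulates the screening design: each chemical is tested as two
blinded duplicate samples over a 4-point dilution series (default
2.2/6.7/20/60 µM, one well per endpoint per concentration), with 8 vehicle
wells per plate and one plate per (endpoint, batch of chemicals).
Measurement noise is multiplicative lognormal on raw values, so normalized
Log10Ratios are Normal around the planted effect.  Chemicals are drawn from
archetypes that mirror the activity classes seen in such screens:

* ``inactive`` — no planted effects (the large majority of a typical screen);
* ``nonspecific_cytotoxic`` — k cytotoxicity-role endpoints suppressed at the
  top concentration;
* ``cyclosporine_like`` — strong suppression of secreted IgG, B/T-cell
  proliferation and T/B-co-culture cytokines;
* ``glucocorticoid_like`` — cytokine suppression (including macrophage IL-10)
  with a serum amyloid A increase in the smooth-muscle system;
* ``antimetabolite_like`` — IgG suppression with broad anti-proliferative
  effects;
* ``single_signature(<name>)`` — the minimal effect pattern raising exactly
  one toxicity alert.

Planted effects are zero at the two lowest concentrations (the baseline pool
for the bmad) and step to their full value at the onset concentration, so
the planted LOEC is exact.  All planted effects point in each endpoint's
canonical response direction.  A :class:`ScreenTruth` records, per chemical,
the archetype, active endpoints with LOECs, cytotoxicity-endpoint counts,
and expected per-concentration signature flags plus chemical-level
summaries; at ``noise_sd=0`` the full pipeline reproduces it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import N_VEHICLE_WELLS
from .similarity import ReferenceDB
from .vocab import ENDOTHELIAL_SYSTEMS, Vocabulary, default_vocabulary

DEFAULT_CONCENTRATIONS: tuple[float, ...] = (2.2, 6.7, 20.0, 60.0)

#: Archetype proportions of the default synthetic screen; roughly one in five
#: chemicals is bioactive, as in broad environmental-chemical screens.
DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "inactive": 0.79,
    "nonspecific_cytotoxic": 0.05,
    "cyclosporine_like": 0.04,
    "glucocorticoid_like": 0.04,
    "antimetabolite_like": 0.04,
    "single_signature": 0.04,
}

SINGLE_SIGNATURES: tuple[str, ...] = (
    "acute_toxicity", "liver_toxicity", "organ_toxicity", "immunosuppression",
    "thrombosis", "skin_irritation", "skin_sensitization", "skin_rash",
    "vascular_toxicity",
)

#: Preferred order in which the cytotoxic archetype suppresses endpoints:
#: endothelial-system SRB first so the acute-toxicity rule is exercised.
_CYTOTOX_ORDER: tuple[str, ...] = (
    "3C:SRB", "4H:SRB", "LPS:SRB", "Mphg:SRB", "BE3C:SRB", "BF4T:SRB",
    "HDF3CGF:SRB", "KF3CT:SRB", "CASM3C:SRB", "MyoF:SRB", "SAg:SRB",
    "SAg:PBMC Cytotoxicity", "BT:PBMC Cytotoxicity",
)

# |effect| magnitudes (Log10Ratio) per archetype; signs follow each
# endpoint's canonical direction (down endpoints are suppressed).
_ARCHETYPE_MAGNITUDES: dict[str, dict[str, float]] = {
    "inactive": {},
    "cyclosporine_like": {
        "BT:sIgG": 0.8, "BT:Proliferation": 0.5, "BT:sIL-17A": 0.4,
        "BT:sIL-2": 0.4, "BT:sIL-6": 0.4, "BT:sTNFα": 0.4,
        "SAg:Proliferation": 0.5,
    },
    "glucocorticoid_like": {
        "Mphg:sIL-10": 0.5, "BT:sIL-2": 0.5, "BT:sIL-6": 0.5,
        "BT:sTNFα": 0.5, "BT:sIL-17A": 0.5, "BT:sIL-17F": 0.4,
        "SAg:Proliferation": 0.4, "CASM3C:SAA": 0.6,
    },
    "antimetabolite_like": {
        "BT:sIgG": 0.8, "BT:Proliferation": 0.5, "SAg:Proliferation": 0.5,
        "3C:Proliferation": 0.4, "HDF3CGF:Proliferation": 0.4,
        "CASM3C:Proliferation": 0.4,
    },
}

_SINGLE_SIGNATURE_MAGNITUDES: dict[str, dict[str, float]] = {
    "acute_toxicity": {"3C:SRB": 0.4, "4H:SRB": 0.4, "BE3C:SRB": 0.4},
    "liver_toxicity": {"3C:SRB": 0.4},
    "organ_toxicity": {"3C:Proliferation": 0.3},
    "immunosuppression": {"SAg:Proliferation": 0.4},
    "thrombosis": {"3C:TF": 0.4},
    "skin_irritation": {"LPS:PGE2": 0.4},
    "skin_sensitization": {"HDF3CGF:Collagen III": 0.4},
    "skin_rash": {"HDF3CGF:VCAM-1": 0.4},
    "vascular_toxicity": {"CASM3C:SAA": 0.4},
}


@dataclass
class ArchetypeSpec:
    """A chemical archetype: per-endpoint effect series over the dilution points."""

    name: str
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    n_cytotox_endpoints: int = 0

    def effect_at(self, endpoint_id: str, conc_index: int) -> float:
        e = self.effects.get(endpoint_id)
        return float(e[conc_index]) if e is not None else 0.0


def _signed(vocabulary: Vocabulary, endpoint_id: str, magnitude: float) -> float:
    return -magnitude if vocabulary[endpoint_id].is_down_readout else magnitude


def make_archetype(name: str, vocabulary: Vocabulary, *, n_concs: int = 4,
                   onset: int = 2, n_cytotox_endpoints: int = 3,
                   effect_magnitude: float | None = None,
                   sig_name: str | None = None) -> ArchetypeSpec:
    """Build an archetype's effect table.

    ``onset`` is the 0-based concentration index where effects switch on
    (effects are zero below it).  ``effect_magnitude`` overrides every
    planted |effect| with one value.  ``single_signature`` archetypes take
    the alert name in ``sig_name``.
    """
    if name == "nonspecific_cytotoxic":
        pool = [e for e in _CYTOTOX_ORDER if e in vocabulary]
        if n_cytotox_endpoints > len(pool):
            raise ValueError(
                f"cytotoxic archetype needs {n_cytotox_endpoints} endpoints; "
                f"vocabulary has {len(pool)} cytotoxicity-role endpoints")
        mags = {e: 0.5 for e in pool[:n_cytotox_endpoints]}
        full_name = name
    elif name == "single_signature":
        if sig_name not in _SINGLE_SIGNATURE_MAGNITUDES:
            raise ValueError(f"unknown signature {sig_name!r}")
        mags = dict(_SINGLE_SIGNATURE_MAGNITUDES[sig_name])
        full_name = f"single_signature({sig_name})"
    elif name in _ARCHETYPE_MAGNITUDES:
        mags = dict(_ARCHETYPE_MAGNITUDES[name])
        full_name = name
    else:
        raise ValueError(f"unknown archetype {name!r}")

    missing = [e for e in mags if e not in vocabulary]
    if missing:
        raise ValueError(f"archetype {name!r} requires endpoints absent from "
                         f"the vocabulary: {missing}")
    if not 0 <= onset < n_concs:
        raise ValueError("onset must index a tested concentration")

    effects = {}
    for ep, mag in mags.items():
        if effect_magnitude is not None:
            mag = effect_magnitude
        series = np.zeros(n_concs)
        series[onset:] = _signed(vocabulary, ep, mag)
        effects[ep] = series
    n_cyto = sum(1 for e in effects if vocabulary[e].is_cytotox_role)
    return ArchetypeSpec(full_name, effects, n_cyto)


# --------------------------------------------------------------------------
# Ground truth


@dataclass
class ScreenTruth:
    """Planted ground truth of a synthetic screen (exact at noise_sd = 0)."""

    concentrations: tuple[float, ...]
    archetype: dict[str, str]                       # chemical -> archetype name
    samples: dict[str, list[str]]                   # chemical -> sample ids
    active_endpoints: dict[str, dict[str, float]]   # chemical -> {endpoint: loec}
    cytotox_counts: dict[tuple[str, float], int]    # (chemical, conc) -> count
    signature_flags: dict[tuple[str, float, str], tuple[bool, bool]]
    signature_summary: dict[tuple[str, str], tuple[str, float | None]]


def _expected_signature_flags(vals: dict[str, float], vocabulary: Vocabulary
                              ) -> dict[str, tuple[bool, bool]]:
    """Direct transcription of the nine rules for noiseless planted profiles.

    The noiseless envelope collapses to (0, 0), so "outside the envelope"
    reduces to "non-zero".
    """
    def v(ep: str) -> float:
        return vals.get(ep, 0.0)

    def out(ep: str) -> bool:
        return v(ep) != 0.0

    srb_low = [e for e in vocabulary.srb_endpoints if v(e) <= -0.3]
    acute = (len(srb_low) >= 3
             and any(e.split(":")[0] in ENDOTHELIAL_SYSTEMS for e in srb_low))
    flags = {"acute_toxicity": (acute, True)}
    if acute:
        for sig in SINGLE_SIGNATURES[1:]:
            flags[sig] = (False, False)
        return flags

    ok3c = v("3C:SRB") > -0.3
    flags["liver_toxicity"] = (v("3C:SRB") <= -0.3, True)
    flags["organ_toxicity"] = (
        out("3C:Proliferation") and v("3C:Proliferation") < -0.1 and ok3c, True)
    flags["immunosuppression"] = (
        (out("SAg:Proliferation") and v("SAg:Proliferation") < -0.1)
        or (out("BT:sIgG") and v("BT:sIgG") < -0.1
            and out("BT:Proliferation") and v("BT:Proliferation") < -0.1)
        or v("SAg:PBMC Cytotoxicity") < -0.3 or v("BT:PBMC Cytotoxicity") < -0.3,
        True)
    flags["thrombosis"] = (out("3C:TF") and v("3C:TF") > 0.1 and ok3c, True)
    flags["skin_irritation"] = (
        out("LPS:PGE2") and v("LPS:PGE2") > 0.1
        and not (out("LPS:sTNFα") and v("LPS:sTNFα") < 0), True)
    flags["skin_sensitization"] = (
        out("HDF3CGF:Collagen III") and v("HDF3CGF:Collagen III") < -0.1, True)
    flags["skin_rash"] = (
        out("HDF3CGF:VCAM-1") and v("HDF3CGF:VCAM-1") > 0.1, True)
    flags["vascular_toxicity"] = (
        out("CASM3C:SAA") and v("CASM3C:SAA") > 0.1, True)
    return flags


def _summarize(flagged: list[float], evaluable: list[float],
               concs: tuple[float, ...]) -> tuple[str, float | None]:
    top = max(concs)
    if len(flagged) >= 2:
        return "listed_ge", min(flagged)
    if top in flagged:
        return "listed_at_top", top
    if not evaluable:
        return "NA", None
    return "nd", None


def _build_truth(chem_specs: dict[str, ArchetypeSpec],
                 samples: dict[str, list[str]],
                 concentrations: tuple[float, ...],
                 vocabulary: Vocabulary) -> ScreenTruth:
    floor = math.log10(1.2)
    cyto = set(vocabulary.cytotox_endpoints)
    active: dict[str, dict[str, float]] = {}
    counts: dict[tuple[str, float], int] = {}
    sig_flags: dict[tuple[str, float, str], tuple[bool, bool]] = {}
    sig_summary: dict[tuple[str, str], tuple[str, float | None]] = {}

    for chem, spec in chem_specs.items():
        loecs = {}
        for ep, series in spec.effects.items():
            above = np.abs(series) > floor
            if above.any():
                loecs[ep] = float(concentrations[int(np.argmax(above))])
        active[chem] = loecs

        cyto_loecs = [l for e, l in loecs.items() if e in cyto]
        for c in concentrations:
            counts[(chem, c)] = sum(1 for l in cyto_loecs if l <= c)

        per_sig_flagged: dict[str, list[float]] = {s: [] for s in SINGLE_SIGNATURES}
        per_sig_eval: dict[str, list[float]] = {s: [] for s in SINGLE_SIGNATURES}
        for i, c in enumerate(concentrations):
            vals = {ep: float(series[i]) for ep, series in spec.effects.items()}
            flags = _expected_signature_flags(vals, vocabulary)
            for sig, (fl, ev) in flags.items():
                sig_flags[(chem, c, sig)] = (fl, ev)
                if fl:
                    per_sig_flagged[sig].append(c)
                if ev:
                    per_sig_eval[sig].append(c)
        for sig in SINGLE_SIGNATURES:
            sig_summary[(chem, sig)] = _summarize(
                per_sig_flagged[sig], per_sig_eval[sig], concentrations)

    return ScreenTruth(
        concentrations=concentrations,
        archetype={c: s.name for c, s in chem_specs.items()},
        samples=samples,
        active_endpoints=active,
        cytotox_counts=counts,
        signature_flags=sig_flags,
        signature_summary=sig_summary,
    )


# --------------------------------------------------------------------------
# Generators


def _assign_archetypes(n_chemicals: int, mix: dict[str, float],
                       vocabulary: Vocabulary, n_concs: int,
                       effect_magnitude: float | None,
                       n_cytotox_endpoints: int) -> list[ArchetypeSpec]:
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype mix proportions must sum to 1")
    # largest-remainder apportionment for deterministic integer counts
    raw = {k: v * n_chemicals for k, v in mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rem = n_chemicals - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rem]:
        counts[k] += 1

    specs: list[ArchetypeSpec] = []
    single_i = cyto_i = 0
    for name in mix:
        for j in range(counts[name]):
            if name == "single_signature":
                sig = SINGLE_SIGNATURES[single_i % len(SINGLE_SIGNATURES)]
                # alternate onset so both the ">= conc" and top-concentration
                # summarization branches occur
                onset = n_concs - 1 if single_i % 2 else 2
                specs.append(make_archetype(
                    name, vocabulary, n_concs=n_concs, onset=onset,
                    sig_name=sig, effect_magnitude=effect_magnitude))
                single_i += 1
            elif name == "nonspecific_cytotoxic":
                # alternate top-concentration-only and fully cytotoxic
                # chemicals; the latter mask every signature at all
                # concentrations (the NA summarization branch)
                onset = 0 if cyto_i % 2 else n_concs - 1
                specs.append(make_archetype(
                    name, vocabulary, n_concs=n_concs, onset=onset,
                    n_cytotox_endpoints=n_cytotox_endpoints,
                    effect_magnitude=effect_magnitude))
                cyto_i += 1
            else:
                specs.append(make_archetype(
                    name, vocabulary, n_concs=n_concs, onset=2,
                    effect_magnitude=effect_magnitude))
    return specs


def generate_screen(config: PipelineConfig | None = None,
                    n_chemicals: int = 30,
                    archetype_mix: dict[str, float] | None = None,
                    noise_sd: float = 0.05,
                    seed: int = 0,
                    vocabulary: Vocabulary | None = None,
                    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS,
                    n_samples: int = 2,
                    batch_size: int = 10,
                    effect_magnitude: float | None = None,
                    n_cytotox_endpoints: int = 3,
                    ) -> tuple[pd.DataFrame, ScreenTruth]:
    """Generate a well-level synthetic screen and its ground truth.

    Returns the long-format well table (treatments plus 8 vehicle wells per
    plate, one plate per endpoint per batch of chemicals) and the
    :class:`ScreenTruth`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vocabulary = vocabulary or default_vocabulary()
    mix = archetype_mix or DEFAULT_ARCHETYPE_MIX
    n_concs = len(concentrations)
    rng = np.random.default_rng(seed)

    specs = _assign_archetypes(n_chemicals, mix, vocabulary, n_concs,
                               effect_magnitude, n_cytotox_endpoints)
    chemicals = [f"CHEM-{i + 1:04d}" for i in range(n_chemicals)]
    chem_specs = dict(zip(chemicals, specs))
    samples = {c: [f"{c}-r{k + 1}" for k in range(n_samples)] for c in chemicals}

    endpoints = vocabulary.endpoint_ids
    n_ep = len(endpoints)
    # stable per-endpoint baseline signal levels (assay units)
    baselines = 10.0 ** rng.uniform(2.0, 4.0, size=n_ep)
    concs = np.asarray(concentrations, float)

    frames = []
    for b0 in range(0, n_chemicals, batch_size):
        batch = chemicals[b0:b0 + batch_size]
        batch_id = b0 // batch_size
        batch_samples = [s for c in batch for s in samples[c]]
        batch_chems = [c for c in batch for _ in samples[c]]
        n_s = len(batch_samples)

        # planted effects: (samples, concs, endpoints)
        E = np.zeros((n_s, n_concs, n_ep))
        ep_index = {e: j for j, e in enumerate(endpoints)}
        for si, chem in enumerate(batch_chems):
            for ep, series in chem_specs[chem].effects.items():
                E[si, :, ep_index[ep]] = series

        noise = rng.normal(0.0, noise_sd, size=E.shape)
        raw = baselines[None, None, :] * 10.0 ** (E + noise)

        plate_ids = np.array(
            [f"B{batch_id:02d}-E{j:03d}" for j in range(n_ep)])
        trt = pd.DataFrame({
            "plate_id": np.tile(plate_ids, n_s * n_concs),
            "well_id": [f"T{si:03d}C{ci}" for si in range(n_s)
                        for ci in range(n_concs) for _ in range(n_ep)],
            "sample_id": np.repeat(batch_samples, n_concs * n_ep),
            "chemical_id": np.repeat(batch_chems, n_concs * n_ep),
            "concentration_uM": np.tile(np.repeat(concs, n_ep), n_s),
            "endpoint_id": np.tile(endpoints, n_s * n_concs),
            "raw_value": raw.ravel(),
            "well_role": "treatment",
        })

        vnoise = rng.normal(0.0, noise_sd, size=(N_VEHICLE_WELLS, n_ep))
        vraw = baselines[None, :] * 10.0 ** vnoise
        veh = pd.DataFrame({
            "plate_id": np.tile(plate_ids, N_VEHICLE_WELLS),
            "well_id": [f"V{w:02d}" for w in range(N_VEHICLE_WELLS)
                        for _ in range(n_ep)],
            "sample_id": "VEHICLE",
            "chemical_id": "DMSO",
            "concentration_uM": 0.0,
            "endpoint_id": np.tile(endpoints, N_VEHICLE_WELLS),
            "raw_value": vraw.ravel(),
            "well_role": "vehicle_control",
        })
        frames.append(trt)
        frames.append(veh)

    wells = pd.concat(frames, ignore_index=True)
    truth = _build_truth(chem_specs, samples, tuple(concentrations), vocabulary)
    return wells, truth


def generate_historical_controls(vocabulary: Vocabulary | None = None,
                                 n_runs: int = 23,
                                 wells_per_run: int = 8,
                                 noise_sd: float = 0.05,
                                 seed: int = 0) -> pd.DataFrame:
    """Historical vehicle-control Log10Ratios, Normal(0, noise_sd) per endpoint.

    Defaults mirror a two-year collection of 23 experimental runs with 8
    vehicle wells each.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    vocabulary = vocabulary or default_vocabulary()
    rng = np.random.default_rng(seed)
    n = n_runs * wells_per_run
    endpoints = vocabulary.endpoint_ids
    values = rng.normal(0.0, noise_sd, size=(n, len(endpoints)))
    return pd.DataFrame({
        "endpoint_id": np.tile(endpoints, n),
        "run": np.repeat(np.arange(n) // wells_per_run, len(endpoints)),
        "log10_ratio": values.ravel(),
    })


def generate_reference_db(archetypes: dict[str, ArchetypeSpec],
                          n_per_archetype: int = 1,
                          noise_sd: float = 0.05,
                          seed: int = 0,
                          vocabulary: Vocabulary | None = None,
                          concentration: float = 60.0,
                          conc_index: int = -1) -> ReferenceDB:
    """Labeled reference profiles around archetype mean effect vectors."""
    vocabulary = vocabulary or default_vocabulary()
    rng = np.random.default_rng(seed)
    endpoints = vocabulary.endpoint_ids
    floor = math.log10(1.2)
    cyto = set(vocabulary.cytotox_endpoints)

    rows, index, n_cyto, mech = [], [], [], []
    for label, spec in archetypes.items():
        mean = np.array([spec.effect_at(e, conc_index) for e in endpoints])
        planted_cyto = sum(
            1 for e in endpoints
            if e in cyto and abs(spec.effect_at(e, conc_index)) > floor)
        for j in range(n_per_archetype):
            rows.append(mean + rng.normal(0.0, noise_sd, size=len(endpoints)))
            index.append((f"{label}#{j + 1}", concentration))
            n_cyto.append(planted_cyto)
            mech.append(spec.name)
    values = pd.DataFrame(
        rows, columns=endpoints,
        index=pd.MultiIndex.from_tuples(index, names=["label", "concentration"]),
    )
    return ReferenceDB(values,
                       pd.Series(n_cyto, index=values.index, name="n_cytotox"),
                       pd.Series(mech, index=values.index, name="mechanism"))


# --------------------------------------------------------------------------
# Scoring against the planted truth


def score_hitcalls(hits: pd.DataFrame, truth: ScreenTruth
                   ) -> tuple[float, float]:
    """Hit-call sensitivity and specificity against the planted truth.

    Computed over every sample × endpoint pair: a pair is truly active when
    its chemical's archetype plants a supra-cutoff effect on that endpoint.
    """
    chem_active = {c: set(eps) for c, eps in truth.active_endpoints.items()}
    chem = hits["chemical_id"]
    is_active = np.array([
        ep in chem_active.get(c, set())
        for c, ep in zip(chem, hits["endpoint_id"])
    ])
    called = hits["hitc"].to_numpy() == 1
    tp = int((is_active & called).sum())
    fn = int((is_active & ~called).sum())
    tn = int((~is_active & ~called).sum())
    fp = int((~is_active & called).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec
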