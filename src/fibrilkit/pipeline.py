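"""Study orchestration: manifests, per-condition analysis, reports, rankings.

A *study* is a set of conditions (an IL-free control plus ionic-liquid
conditions at one or more concentrations), each pointing at kinetics traces,
AFM height maps, and/or an amide-I spectrum.  ``run_study`` executes the
three analysis stages per condition, aggregates the results into report
tables mirroring the standard presentation (kinetic parameters with
uncertainties, z_90% morphometry, secondary-structure percentages), and
tests the anion ordering against the electroselectivity series.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, afm, datasets, ftir, io, kinetics, synthetic
from .errors import FibrilkitError, ManifestError, ValidationError

__all__ = [
    "StudyConfig",
    "ConditionEntry",
    "StudyManifest",
    "ReportBundle",
    "run_study",
    "compare_to_series",
    "simulate_study",
]

logger = logging.getLogger("fibrilkit")

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class StudyConfig:
    """Every tunable threshold of the three stages, with package defaults.

    Attributes mirror the stage parameters: the 20% relative-uncertainty
    flagging gate for sigmoid fits, the 3-sigma segmentation threshold and
    10-px minimum grain area for AFM, the Savitzky-Golay window for FTIR,
    and the bootstrap size/seed for z_90% uncertainties.
    """

    seed: int = 0
    fit_flag_threshold: float = 0.20
    fit_target: str = "mean"  # which fit populates the main table: mean|replicate
    flatten_method: str = "plane"
    segment_threshold_nm: float | None = None  # None -> 3 x robust noise sd
    min_area_nm2: float | None = None  # None -> 10 pixels
    z_quantile: float = 0.90
    n_boot: int = 500
    sg_window_pts: int = 20
    reference_series: tuple[str, ...] = kinetics.ELECTROSELECTIVITY_SERIES

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ConditionEntry:
    """One manifest row: a condition label and its per-modality file paths."""

    label: str
    control: bool = False
    kinetics: str | None = None
    afm: tuple[str, ...] = ()
    ftir: str | None = None


@dataclass(frozen=True)
class StudyManifest:
    """Declarative description of a study: conditions and the reference series."""

    conditions: tuple[ConditionEntry, ...]
    reference_series: tuple[str, ...] = kinetics.ELECTROSELECTIVITY_SERIES
    root: Path = Path(".")

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ManifestError("manifest has no conditions")
        controls = [c for c in self.conditions if c.control]
        if len(controls) != 1:
            raise ManifestError(
                f"manifest must declare exactly one control, found {len(controls)}"
            )
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ManifestError("condition labels must be unique")
        for cond in self.conditions:
            kinetics.parse_condition(cond.label)  # vocabulary check
            for p in self._paths(cond):
                if not (self.root / p).exists():
                    raise ManifestError(f"{cond.label}: missing file {p}")

    @staticmethod
    def _paths(cond: ConditionEntry) -> list[str]:
        out = list(cond.afm)
        if cond.kinetics:
            out.append(cond.kinetics)
        if cond.ftir:
            out.append(cond.ftir)
        return out

    @property
    def control(self) -> ConditionEntry:
        return next(c for c in self.conditions if c.control)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "conditions" not in raw:
            raise ManifestError(f"{path}: manifest needs a 'conditions' list")
        conds = []
        for entry in raw["conditions"]:
            conds.append(
                ConditionEntry(
                    label=str(entry["label"]),
                    control=bool(entry.get("control", False)),
                    kinetics=entry.get("kinetics"),
                    afm=tuple(entry.get("afm", []) or []),
                    ftir=entry.get("ftir"),
                )
            )
        series = tuple(raw.get("reference_series", kinetics.ELECTROSELECTIVITY_SERIES))
        return cls(conditions=tuple(conds), reference_series=series, root=path.parent)


@dataclass
class ReportBundle:
    """All study outputs: report tables, rankings, fits, and run metadata."""

    kinetics_table: pd.DataFrame
    replicate_table: pd.DataFrame
    morphometry_table: pd.DataFrame
    structure_table: pd.DataFrame
    rankings: dict
    metadata: dict
    failures: list[dict] = field(default_factory=list)
    fits: dict = field(default_factory=dict)


def _fit_condition_kinetics(
    traces: list[kinetics.KineticTrace], config: StudyConfig
) -> tuple[kinetics.SigmoidFit, list[kinetics.SigmoidFit]]:
    """Fit the replicate mean and each replicate of one condition."""
    rep_fits = [
        kinetics.fit_sigmoid(tr, flag_threshold=config.fit_flag_threshold)
        for tr in traces
    ]
    rset = kinetics.aggregate_replicates(traces)
    mean_fit = kinetics.fit_sigmoid(
        rset.mean_trace, flag_threshold=config.fit_flag_threshold
    )
    return mean_fit, rep_fits


def _kinetics_row(fit: kinetics.SigmoidFit, n_replicates: int) -> dict:
    return {
        "condition": fit.condition,
        "t_lag_min": fit.t_lag,
        "t_lag_err": fit.uncertainties.get("t_lag", np.nan),
        "t_half_min": fit.t_half,
        "t_half_err": fit.uncertainties.get("t_half", np.nan),
        "k_agg_min_inv": fit.k_agg,
        "k_agg_err": fit.k_agg_uncertainty,
        "residual_rms": fit.residual_rms,
        "converged": fit.converged,
        "flagged": fit.flagged,
        "n_replicates": n_replicates,
    }


def run_study(
    manifest: StudyManifest,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Execute all three stages over a manifest and assemble report tables.

    Per-condition failures are logged and recorded in ``bundle.failures``;
    they never silently abort the remaining conditions.  When ``out_dir`` is
    given, the tables are written as CSV with fixed numeric formatting plus
    a JSON metadata record, so identical inputs/config/seed give
    byte-identical files.
    """
    config = config or StudyConfig()
    kin_rows, rep_rows, morph_rows, struct_rows = [], [], [], []
    failures: list[dict] = []
    fits: dict[str, kinetics.SigmoidFit] = {}

    for cond in manifest.conditions:
        if cond.kinetics:
            try:
                traces = io.read_kinetics_csv(manifest.root / cond.kinetics)
                traces = [tr for tr in traces if tr.condition == cond.label] or traces
                mean_fit, rep_fits = _fit_condition_kinetics(traces, config)
                main = mean_fit if config.fit_target == "mean" else rep_fits[0]
                fits[cond.label] = main
                kin_rows.append(_kinetics_row(main, len(traces)))
                for rf in rep_fits:
                    row = _kinetics_row(rf, 1)
                    row["replicate"] = rf.replicate
                    rep_rows.append(row)
            except FibrilkitError as exc:
                failures.append(
                    {"condition": cond.label, "stage": "kinetics", "reason": str(exc)}
                )
                logger.warning("kinetics failed for %s: %s", cond.label, exc)
        else:
            logger.info("no kinetics files for %s; skipping stage", cond.label)

        if cond.afm:
            try:
                grain_tables = []
                for p in cond.afm:
                    hmap = io.read_heightmap(manifest.root / p)
                    flat = afm.flatten(hmap, method=config.flatten_method)
                    grain_tables.append(
                        afm.segment_objects(
                            flat,
                            threshold=config.segment_threshold_nm,
                            min_area=config.min_area_nm2,
                        )
                    )
                dist = afm.height_distribution(grain_tables)
                z90, z90_err = afm.bootstrap_z90(
                    dist, n_boot=config.n_boot, seed=config.seed, q=config.z_quantile
                )
                morph_rows.append(
                    {
                        "condition": cond.label,
                        "n_images": len(cond.afm),
                        "n_objects": dist.n_objects,
                        "z90_nm": z90,
                        "z90_err_nm": z90_err,
                    }
                )
            except FibrilkitError as exc:
                failures.append(
                    {"condition": cond.label, "stage": "afm", "reason": str(exc)}
                )
                logger.warning("morphometry failed for %s: %s", cond.label, exc)
        else:
            logger.info("no AFM files for %s; morphometry skipped", cond.label)

        if cond.ftir:
            try:
                spectrum = io.read_spectrum_csv(manifest.root / cond.ftir)
                model, content = ftir.deconvolve(spectrum)
                struct_rows.append(
                    {
                        "condition": cond.label,
                        **{f"{k}_pct": v for k, v in content.as_dict().items()},
                        "n_components": len(model.components),
                        "residual_rms": model.residual_rms,
                    }
                )
            except FibrilkitError as exc:
                failures.append(
                    {"condition": cond.label, "stage": "ftir", "reason": str(exc)}
                )
                logger.warning("deconvolution failed for %s: %s", cond.label, exc)
        else:
            logger.info("no FTIR file for %s; deconvolution skipped", cond.label)

    rankings = _rank_all(fits, manifest.reference_series)

    metadata = {
        "fibrilkit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "n_conditions": len(manifest.conditions),
        "failures": failures,
    }
    bundle = ReportBundle(
        kinetics_table=pd.DataFrame(kin_rows),
        replicate_table=pd.DataFrame(rep_rows),
        morphometry_table=pd.DataFrame(morph_rows),
        structure_table=pd.DataFrame(struct_rows),
        rankings=rankings,
        metadata=metadata,
        failures=failures,
        fits=fits,
    )
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def _rank_all(fits: dict, reference_series: tuple[str, ...]) -> dict:
    """Ordering test per concentration with >= 2 IL conditions."""
    by_conc: dict[float, dict] = {}
    for label, fit in fits.items():
        anion, conc = kinetics.parse_condition(label)
        if anion is not None:
            by_conc.setdefault(conc, {})[label] = fit
    rankings: dict[str, dict] = {}
    for conc, group in sorted(by_conc.items()):
        if len(group) < 2:
            continue
        per_param = {}
        for param in ("t_lag", "t_half", "k_agg"):
            order, match = kinetics.rank_conditions(
                group, param, reference_series=reference_series
            )
            per_param[param] = {"order": order, "match": match}
        rankings[f"{conc:g} mM"] = per_param
    return rankings


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the report tables (CSV, fixed float format) and metadata (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "kinetics_table.csv": bundle.kinetics_table,
        "kinetics_replicates.csv": bundle.replicate_table,
        "morphometry_table.csv": bundle.morphometry_table,
        "structure_table.csv": bundle.structure_table,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)
    io.write_json(out / "rankings.json", bundle.rankings)
    io.write_json(out / "run_metadata.json", bundle.metadata)


def compare_to_series(
    bundle: ReportBundle, concentration: float, parameter: str = "t_half"
) -> str:
    """Verdict for one concentration: forward-match, reverse-match, or no-match.

    A *reverse* match of the electroselectivity series (most surface-active
    anion fastest) is the signature of direct anion-protein surface binding.
    """
    key = f"{concentration:g} mM"
    if key not in bundle.rankings:
        raise ValidationError(f"no ranking available at {key}")
    match = bundle.rankings[key][parameter]["match"]
    return {"forward": "forward-match", "reverse": "reverse-match"}.get(
        match, "no-match"
    )


# --- synthetic study --------------------------------------------------------

#: Morphology presets per anion, emulating the observed 25 mM fibril fields:
#: needle-like control/AC/Cl fields, laterally associated NO3/BF4 fibrils,
#: and HSO4-induced large clusters.
_MORPHOLOGY_PRESETS: dict[str | None, dict] = {
    None: {"association_prob": 0.05, "cluster_prob": 0.0},
    "AC": {"association_prob": 0.15, "cluster_prob": 0.0},
    "Cl": {"association_prob": 0.10, "cluster_prob": 0.0},
    "NO3": {"association_prob": 0.70, "cluster_prob": 0.05},
    "BF4": {"association_prob": 0.60, "cluster_prob": 0.05},
    "HSO4": {"association_prob": 0.20, "cluster_prob": 0.50},
}


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    concentration: float = 25.0,
    noise_sd: float = 0.02,
    afm_size_px: int = 1024,
    n_fibrils: int = 120,
    ftir_state: str = "fibril",
) -> Path:
    """Generate a complete synthetic study from the reference presets.

    Writes kinetics CSVs, AFM ASCII maps, spectrum CSVs, a ground-truth JSON
    sidecar, and a ``manifest.yaml``; returns the manifest path.  Kinetic
    parameters and structure compositions come from the reference tables at
    the requested concentration; AFM morphology presets emulate the
    per-anion fibril phenotypes (needles, lateral association, clusters).
    """
    out = Path(out_dir)
    for sub in ("kinetics", "afm", "ftir"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    kin_ref = datasets.load_kinetics_reference()
    struct_ref = datasets.load_structure_reference()

    sel = []
    for _, row in kin_ref.iterrows():
        anion, conc = kinetics.parse_condition(row["condition"])
        if anion is None or conc == concentration:
            sel.append(row)

    entries, truth = [], {}
    for i, row in enumerate(sel):
        label = str(row["condition"])
        anion, _ = kinetics.parse_condition(label)
        slug = label.replace(" ", "_").replace("[", "").replace("]", "")
        cond_seed = seed * 1009 + i * 17  # distinct, reproducible per-condition seeds

        kspec = synthetic.kinetics_spec_from_reference(
            row, seed=cond_seed, noise_sd=noise_sd
        )
        traces = synthetic.make_kinetics(kspec)
        kin_path = f"kinetics/{slug}.csv"
        io.write_kinetics_csv(out / kin_path, traces)

        morph = _MORPHOLOGY_PRESETS.get(anion, _MORPHOLOGY_PRESETS[None])
        # shrink rod lengths with the field so that down-scaled test fields
        # still accommodate the requested number of disjoint objects
        lscale = min(afm_size_px / 1024.0, 1.0)
        fspec = synthetic.FibrilFieldSpec(
            size_px=afm_size_px,
            n_fibrils=n_fibrils,
            length_range_nm=(100.0 * lscale, 600.0 * lscale),
            seed=cond_seed + 1,
            source_id=slug,
            **morph,
        )
        fld = synthetic.make_fibril_field(fspec)
        afm_path = f"afm/{slug}.txt"
        io.write_heightmap_ascii(out / afm_path, fld.heightmap)

        srow = struct_ref[
            (struct_ref["condition"] == label) & (struct_ref["state"] == ftir_state)
        ]
        if srow.empty and anion is not None:
            # structure reference is reported at 25 mM; reuse the anion's row
            srow = struct_ref[
                struct_ref["condition"].str.contains(anion)
                & (struct_ref["state"] == ftir_state)
            ]
        if srow.empty:
            srow = struct_ref[
                (struct_ref["condition"] == "control")
                & (struct_ref["state"] == ftir_state)
            ]
        sspec = synthetic.spectrum_spec_from_reference(
            srow.iloc[0], seed=cond_seed + 2, noise_sd=0.01
        )
        spectrum = synthetic.make_spectrum(sspec)
        ftir_path = f"ftir/{slug}.csv"
        io.write_spectrum_csv(out / ftir_path, spectrum)

        entries.append(
            {
                "label": label,
                "control": anion is None,
                "kinetics": kin_path,
                "afm": [afm_path],
                "ftir": ftir_path,
            }
        )
        truth[label] = {
            "kinetics": {
                "t_lag": kspec.t_lag,
                "t_half": kspec.t_half,
                "k_agg": kinetics.aggregation_rate(kspec.t_lag, kspec.t_half),
                "noise_sd": kspec.noise_sd,
            },
            "afm": {
                "n_objects": int(len(fld.truth)),
                "object_heights_nm": [
                    round(h, 4) for h in fld.truth["max_height_nm"].tolist()
                ],
                **morph,
            },
            "ftir": {"fractions": sspec.fractions},
        }

    manifest_payload = {
        "reference_series": list(kinetics.ELECTROSELECTIVITY_SERIES),
        "conditions": entries,
    }
    manifest_path = out / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest_payload, fh, sort_keys=False)
    io.write_json(out / "ground_truth.json", truth)
    return manifest_path
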