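"""Config-driven orchestration of the full workflow:

snap homes -> 1 km reach -> three buffers -> BEM table -> value comparisons
-> mixed-model association fits per stratum -> coefficient z tests ->
significance-agreement tables -> manifest.

Outputs are deterministic under a fixed config and seed: re-running writes
byte-identical tables, and the manifest records a config hash plus per-stage
row counts and output checksums so any stage can be audited or re-run from
its intermediate files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bem import BEM_COLUMNS, BemContext, compute_bem_table
from .buffers import METHODS, build_buffers, write_buffers
from .comparison import (
    DEFAULT_ALPHA,
    AssociationFit,
    ComparisonError,
    compare_bem_vectors,
    compare_coefficients,
    fit_association,
    tabulate_agreement,
)
from .geodata import (
    OUTCOME_NAMES,
    load_network,
    load_parcels,
    load_parks,
    load_participants,
    load_points,
    filter_walkable,
    participants_to_frame,
)
from .service_area import DEFAULT_CUTOFF, reachable_subnetwork, snap_to_network
from .synthetic_city import CityConfig, OutcomeModelConfig, generate_city, write_city

logger = logging.getLogger(__name__)

DEFAULT_METHOD_PAIRS = (("sausage", "detailed_trimmed"), ("sausage", "detailed"))
COVARIATE_COLUMNS = (
    "age", "gender", "education", "marital_status", "employed",
    "ses_stratum", "walkability_stratum",
)


class PipelineError(Exception):
    pass


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML or JSON."""

    # either file inputs ...
    network_path: str | None = None
    parcels_path: str | None = None
    points_path: str | None = None
    parks_path: str | None = None
    participants_path: str | None = None
    # ... or a synthetic city
    synth: bool = True
    synth_n: int = 400
    synth_clusters: int = 20
    seed: int = 0

    cutoff: float = DEFAULT_CUTOFF
    trims: tuple[float, ...] = (25.0,)
    methods: tuple[str, ...] = METHODS
    detailed_closing: float | None = None  # None: trim + 275 m
    dt_closing: float | None = None        # None: trim + 25 m
    snapped_points: bool = True
    strata: str = "pooled"  # pooled | quadrant
    alpha: float = DEFAULT_ALPHA
    all_pairs: bool = False
    out_dir: str = "bufcomp_out"

    def validate(self) -> None:
        if len(self.methods) < 2:
            raise PipelineError("at least 2 buffer methods are required for any comparison")
        if any(t <= 0 for t in self.trims):
            raise PipelineError("trims must be positive")
        if self.strata not in ("pooled", "quadrant"):
            raise PipelineError(f"unknown strata mode {self.strata!r}")
        if not self.synth:
            required = (self.network_path, self.parcels_path, self.points_path,
                        self.parks_path, self.participants_path)
            if any(p is None for p in required):
                raise PipelineError("file inputs incomplete and synth disabled")

    def method_pairs(self) -> list[tuple[str, str]]:
        if self.all_pairs:
            return [(a, b) for i, a in enumerate(self.methods) for b in self.methods[i + 1:]]
        return [p for p in DEFAULT_METHOD_PAIRS if p[0] in self.methods and p[1] in self.methods]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trims", "methods"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def canonical_json(self) -> str:
        """Canonical serialization for the config hash.

        ``out_dir`` is excluded: the hash identifies the analysis, not where
        its results are written.
        """
        doc = dataclasses.asdict(self)
        doc.pop("out_dir")
        return json.dumps(doc, sort_keys=True, default=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _strata_frames(pdf: pd.DataFrame, mode: str) -> dict[str, pd.DataFrame]:
    if mode == "pooled":
        return {"pooled": pdf}
    for col in ("ses_stratum", "walkability_stratum"):
        if pdf[col].isna().any() or (pdf[col] == "").any():
            raise PipelineError(f"strata mode 'quadrant' requires non-empty {col} labels")
    out = {"pooled": pdf}
    for ses in ("low", "high"):
        for walk in ("low", "high"):
            sub = pdf[(pdf.ses_stratum == ses) & (pdf.walkability_stratum == walk)]
            out[f"ses_{ses}/walk_{walk}"] = sub
    return out


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # --- stage: inputs -----------------------------------------------------
    if config.synth:
        city = generate_city(
            n=config.synth_n, n_clusters=config.synth_clusters, seed=config.seed
        )
        net, parcels, points, parks = city.net, city.parcels, city.points, city.parks
        participants = city.participants
        write_city(city, out_dir / "synth")
    else:
        net = load_network(config.network_path)
        parcels = load_parcels(config.parcels_path)
        points = load_points(config.points_path)
        parks = load_parks(config.parks_path)
        participants = load_participants(config.participants_path)
    walkable = filter_walkable(net)
    manifest["stages"]["inputs"] = {
        "participants": len(participants),
        "edges": net.n_edges,
        "walkable_edges": walkable.n_edges,
        "parcels": len(parcels),
        "points": len(points),
        "parks": len(parks),
    }

    # --- stage: snap + reach + buffers ------------------------------------
    buffers = []
    long_snaps = 0
    for p in participants:
        loc = snap_to_network((p.x, p.y), walkable)
        if loc.snap_distance > 500.0:
            long_snaps += 1
        reach = reachable_subnetwork(walkable, loc, config.cutoff)
        for trim in config.trims:
            buffers.extend(
                build_buffers(
                    reach, p.id, trim, config.methods,
                    config.detailed_closing, config.dt_closing,
                ).values()
            )
    write_buffers(buffers, out_dir / "buffers.geojson")
    manifest["stages"]["buffers"] = {"count": len(buffers), "long_snaps": long_snaps}

    # --- stage: BEM table --------------------------------------------------
    ctx = BemContext(
        net=walkable, parcels=parcels, points=points, parks=parks,
        snapped=config.snapped_points,
    )
    bem_table = compute_bem_table(buffers, ctx)
    bem_table.to_csv(out_dir / "bem.csv", index=False)
    manifest["stages"]["bem"] = {"rows": len(bem_table)}

    # --- stage: value-level comparisons -----------------------------------
    value_rows = []
    for trim in config.trims:
        for m1, m2 in config.method_pairs():
            for pc in compare_bem_vectors(bem_table, m1, m2, BEM_COLUMNS, trim):
                value_rows.append({
                    "trim": trim, "bem": pc.bem, "method_1": pc.method_1,
                    "method_2": pc.method_2, "t": pc.t, "df": pc.df, "p": pc.p,
                    "mse": pc.mse, "n": pc.n, "status": pc.status,
                })
    value_df = pd.DataFrame(value_rows)
    value_df.to_csv(out_dir / "bem_comparisons.csv", index=False)
    manifest["stages"]["value_comparisons"] = {"rows": len(value_df)}

    # --- stage: association fits ------------------------------------------
    pdf = participants_to_frame(participants)
    trim0 = config.trims[0]  # association models use the primary trim
    fits: dict[tuple, AssociationFit] = {}
    skipped = 0
    for stratum, sub in _strata_frames(pdf, config.strata).items():
        if len(sub) < 30 or sub["cluster_id"].nunique() < 2:
            logger.warning("stratum %s too small for modeling; skipped", stratum)
            continue
        ids = sub["participant_id"].tolist()
        covs = sub[list(COVARIATE_COLUMNS)].reset_index(drop=True)
        clusters = sub["cluster_id"].to_numpy()
        for method in config.methods:
            mt = bem_table[(bem_table.method == method) & (bem_table.trim == trim0)]
            mt = mt.set_index("participant_id").loc[ids]
            for bem_name in BEM_COLUMNS:
                values = mt[bem_name].to_numpy(float)
                sd = values.std(ddof=1)
                if sd == 0 or not np.isfinite(sd):
                    skipped += 1
                    continue
                z = (values - values.mean()) / sd
                for outcome in OUTCOME_NAMES:
                    fit = fit_association(
                        sub[outcome].to_numpy(float), z, clusters, covs,
                        outcome_name=outcome, bem_name=bem_name, method=method,
                        trim=trim0, stratum=stratum,
                    )
                    if fit.converged:
                        fits[(stratum, method, bem_name, outcome)] = fit
                    else:
                        skipped += 1
    fit_df = pd.DataFrame([dataclasses.asdict(f) for f in fits.values()])
    fit_df.to_csv(out_dir / "association_fits.csv", index=False)
    manifest["stages"]["association_fits"] = {"rows": len(fit_df), "skipped": skipped}

    # --- stage: coefficient comparisons + agreement ------------------------
    comparisons = []
    comp_rows = []
    for (stratum, method, bem_name, outcome), fit1 in fits.items():
        for m1, m2 in config.method_pairs():
            if method != m1:
                continue
            fit2 = fits.get((stratum, m2, bem_name, outcome))
            if fit2 is None:
                continue
            cc = compare_coefficients(fit1, fit2, config.alpha)
            comparisons.append(cc)
            comp_rows.append({
                "stratum": stratum, "bem": bem_name, "outcome": outcome,
                "method_1": m1, "method_2": m2,
                "coef_1": fit1.coef, "se_1": fit1.se, "p_1": fit1.p,
                "coef_2": fit2.coef, "se_2": fit2.se, "p_2": fit2.p,
                "delta": cc.delta, "z": cc.z, "p": cc.p, "status": cc.status,
            })
    comp_df = pd.DataFrame(comp_rows)
    comp_df.to_csv(out_dir / "coef_comparisons.csv", index=False)
    agreement = tabulate_agreement(comparisons)
    agreement.to_csv(out_dir / "agreement.csv", index=False)

    summary = {
        "alpha": config.alpha,
        "by_stratum_pair": agreement.to_dict(orient="records"),
        "by_outcome": _breakdown(comp_df, "outcome"),
        "by_bem": _breakdown(comp_df, "bem"),
    }
    with open(out_dir / "agreement.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest["stages"]["coef_comparisons"] = {"rows": len(comp_df)}

    outputs = ["buffers.geojson", "bem.csv", "bem_comparisons.csv",
               "association_fits.csv", "coef_comparisons.csv", "agreement.csv",
               "agreement.json"]
    manifest["outputs"] = {name: _sha256(out_dir / name) for name in outputs}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _breakdown(comp_df: pd.DataFrame, key: str) -> list[dict]:
    if comp_df.empty:
        return []
    rows = []
    for (value, m1, m2), grp in comp_df.groupby([key, "method_1", "method_2"]):
        rows.append({
            key: value, "method_pair": f"{m1}_vs_{m2}", "n_pairs": int(len(grp)),
            "n_any_significant": int((grp.status != "neither").sum()),
            "n_differing": int(grp.status.isin(["only_method_1", "only_method_2"]).sum()),
        })
    return rows
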