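"""End-to-end orchestration: decays -> distributions -> restraints -> validation.

A single TOML config drives the run; outputs (TSV tables, a GROMACS restraint
file and a JSON run report carrying the config hash) are deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .decay_fit import fit_distance_distribution, fit_donor
from .decay_io import read_decay
from .restraints import (
    FretTableRow,
    build_restraints,
    read_fret_table,
    score_restraints,
    write_distance_restraints,
)
from .sitemap import SiteMap
from .structure_metrics import compare_to_fret, pocket_openness
from .structures import StructureModel

STAGES = ("fit", "table", "restraints", "validate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    state: str
    output_dir: Path
    seed: int = 0
    table_path: Path | None = None
    scheme: str = "paper-default"
    temperature: float = 300.0
    decay_pairs: list[dict] = field(default_factory=list)
    structure_path: Path | None = None
    sitemap_path: Path | None = None
    pocket_threshold: float = 24.0
    tolerance_frac: float = 0.10
    config_hash: str = ""

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = path.read_bytes()
        cfg = tomllib.loads(raw.decode())
        base = path.parent

        def respath(v):
            p = Path(v)
            return p if p.is_absolute() else base / p

        table = cfg.get("tables", {}).get("fret")
        structure = cfg.get("structure", {})
        run = cls(
            state=cfg.get("state", "ca_saturated"),
            output_dir=respath(cfg.get("output_dir", "fretmd_out")),
            seed=int(cfg.get("seed", 0)),
            table_path=respath(table) if table else None,
            scheme=cfg.get("restraints", {}).get("scheme", "paper-default"),
            temperature=float(cfg.get("restraints", {}).get("temperature", 300.0)),
            decay_pairs=cfg.get("decays", {}).get("pairs", []),
            structure_path=respath(structure["file"]) if "file" in structure else None,
            sitemap_path=respath(structure["sitemap"]) if "sitemap" in structure else None,
            pocket_threshold=float(structure.get("pocket_threshold", 24.0)),
            tolerance_frac=float(structure.get("tolerance_frac", 0.10)),
            config_hash=hashlib.sha256(raw).hexdigest()[:16],
        )
        if run.state not in ("ca_free", "ca_saturated"):
            raise PipelineError(f"[config] unknown state {run.state!r}")
        for p in (run.table_path, run.structure_path, run.sitemap_path):
            if p is not None and not p.exists():
                raise PipelineError(f"[config] missing input file: {p}")
        for pair in run.decay_pairs:
            for key in ("donor_file", "da_file"):
                f = respath(pair[key])
                if not f.exists():
                    raise PipelineError(f"[fit] missing decay file: {f}")
                pair[key] = str(f)
        if run.table_path is None and not run.decay_pairs:
            raise PipelineError("[config] need a FRET table or decay pairs")
        return run


def _fit_stage(config: RunConfig) -> tuple[list[FretTableRow], pd.DataFrame]:
    rows: list[FretTableRow] = []
    records = []
    for pair in config.decay_pairs:
        try:
            donor_curve = read_decay(pair["donor_file"])
            da_curve = read_decay(pair["da_file"])
            donor, donor_chi2 = fit_donor(
                donor_curve, int(pair.get("components", 1))
            )
            fit = fit_distance_distribution(da_curve, donor, float(pair["r0"]))
        except Exception as exc:
            raise PipelineError(f"[fit] {pair.get('name', '?')}: {exc}") from exc
        rows.append(
            FretTableRow(
                donor_site=(pair["subunit_d"], int(pair["res_d"])),
                acceptor_site=(pair["subunit_a"], int(pair["res_a"])),
                state=pair.get("state", config.state),
                rbar=fit.distribution.rbar,
                hw=fit.distribution.hw,
            )
        )
        records.append(
            {
                "name": pair.get("name", f"{pair['subunit_d']}{pair['res_d']}-"
                                          f"{pair['subunit_a']}{pair['res_a']}"),
                "rbar_A": fit.distribution.rbar,
                "hw_A": fit.distribution.hw,
                "rbar_se_A": fit.uncertainty["rbar"],
                "hw_se_A": fit.uncertainty["hw"],
                "chi2_red": fit.chi2_red,
                "donor_chi2_red": donor_chi2,
                "converged": fit.converged,
            }
        )
    return rows, pd.DataFrame(records)


def run_pipeline(config: RunConfig) -> dict:
    """Execute fit -> table -> restraints -> (optional) validation.

    Returns the run report (also written as JSON into the output directory).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "fretmd_version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "state": config.state,
        "stages": {},
    }

    rows: list[FretTableRow] = []
    if config.decay_pairs:
        fitted_rows, fit_table = _fit_stage(config)
        rows.extend(fitted_rows)
        fit_path = out / "decay_fits.tsv"
        fit_table.to_csv(fit_path, sep="\t", index=False)
        report["stages"]["fit"] = {
            "n_pairs": len(fitted_rows), "output": fit_path.name
        }

    if config.table_path is not None:
        try:
            rows.extend(read_fret_table(config.table_path))
        except Exception as exc:
            raise PipelineError(f"[table] {config.table_path}: {exc}") from exc
    report["stages"]["table"] = {"n_rows": len(rows)}

    site_map = (
        SiteMap.from_toml(config.sitemap_path)
        if config.sitemap_path is not None
        else default_sitemap()
    )
    structure = (
        StructureModel.from_file(config.structure_path)
        if config.structure_path is not None
        else None
    )

    try:
        records = build_restraints(
            rows,
            state=config.state,
            site_map=site_map,
            scheme=config.scheme,
            temperature=config.temperature,
            structure=structure,
        )
        itp_path = out / f"restraints_{config.state}.itp"
        warnings = write_distance_restraints(records, itp_path)
        tsv_path = out / f"restraints_{config.state}.tsv"
        pd.DataFrame(
            {
                "label": [r.label for r in records],
                "low_A": [r.low for r in records],
                "up1_A": [r.up1 for r in records],
                "up2_A": [r.up2 for r in records],
                "kfac_kJ_mol_nm2": [r.force_constant for r in records],
            }
        ).to_csv(tsv_path, sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[restraints] {exc}") from exc
    report["stages"]["restraints"] = {
        "n_records": len(records),
        "scheme": config.scheme,
        "outputs": [itp_path.name, tsv_path.name],
        "warnings": warnings,
    }

    if structure is not None:
        try:
            score = score_restraints(structure, records)
            agree = compare_to_fret(
                rows, structure, site_map,
                tolerance_frac=config.tolerance_frac, state=config.state,
            )
            agree_path = out / "fret_agreement.tsv"
            agree.to_csv(agree_path, sep="\t", index=False)
            validation = {
                "fraction_satisfied": score.fraction_satisfied,
                "total_violation_A": score.total_violation,
                "n_within_tolerance": int(agree["within_tolerance"].sum()),
                "outputs": [agree_path.name],
            }
            try:
                pocket = pocket_openness(
                    structure, site_map, threshold=config.pocket_threshold
                )
                validation["pocket"] = {
                    "d_13_51_A": pocket.d_13_51, "state": pocket.state
                }
            except KeyError:
                validation["pocket"] = None  # residues 13/51 not in structure
        except Exception as exc:
            raise PipelineError(f"[validate] {exc}") from exc
        report["stages"]["validate"] = validation

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def packaged_table_path() -> Path:
    """The packaged measured-distance table (45 pairs per Ca2+ state)."""
    return Path(__file__).parent / "data" / "table1.tsv"


def packaged_extra_table_path() -> Path:
    """The packaged literature-distance table (2 extra pairs per state)."""
    return Path(__file__).parent / "data" / "extra_restraints.tsv"


def default_sitemap() -> SiteMap:
    """The packaged troponin site map (1J1E-style chain assignment)."""
    return SiteMap.from_toml(Path(__file__).parent / "data" / "sitemap_1j1e.toml")
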