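"""Config parsing, medium-recipe conversion, and tabular readers/writers.

Medium recipes arrive as flat key-value mappings (YAML or CLI flags)
in bench units — transferrin in ug/mL, chelator complex in umol/L —
and are converted to molar :class:`~ferrispec.speciation.MediumComposition`
pools here, in one place.  Unknown keys are rejected rather than
ignored so a typo cannot silently change a medium.

All delimited output is comma-separated UTF-8 with a header row;
files additionally carry '#'-prefixed metadata lines (package version,
config hash, binding constants) so every number in them is auditable.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .chelators import ChelatorDefinition, effective_betas, get_chelator
from .errors import ConfigError
from .speciation import MediumComposition, SpeciationState, TransferrinParameters

__all__ = [
    "load_config",
    "medium_from_config",
    "scenarios_from_config",
    "constants_metadata",
    "write_table",
    "write_json",
    "read_two_column_table",
    "speciation_table",
]

_MEDIUM_KEYS = {
    "htf_ug_per_ml",
    "atf_ug_per_ml",
    "complex_umol_per_l",
    "chelator_name",
    "ph",
    "bicarbonate_mmol_per_l",
}


def _package_version() -> str:
    try:
        return version("ferrispec")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def load_config(path: str | Path) -> dict:
    """Read a YAML config file into a mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a key-value mapping")
    return cfg


def medium_from_config(
    cfg: dict,
    tf: TransferrinParameters | None = None,
) -> tuple[MediumComposition, ChelatorDefinition | None]:
    """Convert a bench-unit medium recipe to molar pools.

    Recognized keys: ``htf_ug_per_ml`` (diferric transferrin),
    ``atf_ug_per_ml`` (apotransferrin), ``complex_umol_per_l`` (1:1-iron
    chelator complex), ``chelator_name``, ``ph``,
    ``bicarbonate_mmol_per_l``.  Holotransferrin contributes two irons
    per molecule; each chelator complex contributes one iron and
    ``n_max`` ligand monomers.
    """
    if tf is None:
        tf = TransferrinParameters()
    unknown = set(cfg) - _MEDIUM_KEYS
    if unknown:
        raise ConfigError(
            f"unknown medium key(s): {', '.join(sorted(unknown))}"
        )
    htf = float(cfg.get("htf_ug_per_ml", 0.0))
    atf = float(cfg.get("atf_ug_per_ml", 0.0))
    complex_umol = float(cfg.get("complex_umol_per_l", 0.0))
    ph = float(cfg.get("ph", 7.4))
    bicarb = float(cfg.get("bicarbonate_mmol_per_l", 3.5)) * 1e-3

    chelator = None
    if complex_umol > 0 or "chelator_name" in cfg:
        chelator = get_chelator(str(cfg.get("chelator_name", "deferiprone")))

    tf_molar = (htf + atf) * 1e-3 / tf.molar_mass_equivalence
    htf_molar = htf * 1e-3 / tf.molar_mass_equivalence
    fe_total = tf.iron_sites * htf_molar + complex_umol * 1e-6
    ligand_total = (chelator.n_max if chelator else 0) * complex_umol * 1e-6

    comp = MediumComposition(
        tf_total=tf_molar,
        fe_total=fe_total,
        ligand_total=ligand_total,
        ph=ph,
        bicarbonate=bicarb,
    )
    return comp, chelator


#: The reference scenario set: high holotransferrin alone versus
#: growth-limiting holotransferrin topped up with iron-loaded
#: deferiprone at two doses.
DEFAULT_SCENARIOS: tuple[dict, ...] = (
    {"name": "1000 ug/mL hTf", "htf_ug_per_ml": 1000.0},
    {
        "name": "100 ug/mL hTf + 26 uM Def3Fe",
        "htf_ug_per_ml": 100.0,
        "complex_umol_per_l": 26.0,
        "chelator_name": "deferiprone",
    },
    {
        "name": "100 ug/mL hTf + 52 uM Def3Fe",
        "htf_ug_per_ml": 100.0,
        "complex_umol_per_l": 52.0,
        "chelator_name": "deferiprone",
    },
)


def scenarios_from_config(
    cfg: dict | None, tf: TransferrinParameters | None = None
) -> list[tuple[str, MediumComposition, ChelatorDefinition | None]]:
    """Expand a ``{"scenarios": [...]}`` config into named media.

    With ``cfg`` None the built-in reference scenario set is used.
    Each scenario entry is a medium recipe plus a ``name`` key.
    """
    entries = (
        list(DEFAULT_SCENARIOS)
        if cfg is None
        else cfg.get("scenarios")
    )
    if not isinstance(entries, list) or not entries:
        raise ConfigError("config must contain a non-empty 'scenarios' list")
    out = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ConfigError(f"scenario #{i} must be a mapping")
        entry = dict(entry)
        name = str(entry.pop("name", f"scenario-{i}"))
        comp, chel = medium_from_config(entry, tf=tf)
        out.append((name, comp, chel))
    return out


def constants_metadata(
    tf: TransferrinParameters,
    chelator: ChelatorDefinition | None = None,
    *,
    ph: float = 7.4,
    protonation_correction: bool = True,
) -> dict:
    """Audit record of every constant behind a computed output."""
    meta = {
        "package_version": _package_version(),
        "tf_k1_l_per_mol": tf.k1,
        "tf_k2_l_per_mol": tf.k2,
        "tf_molar_mass_equivalence_g_per_mol": tf.molar_mass_equivalence,
        "tf_molar_mass_budget_g_per_mol": tf.molar_mass_budget,
    }
    if chelator is not None:
        meta.update(
            chelator=chelator.name,
            chelator_n_max=chelator.n_max,
            chelator_log_beta=list(chelator.log_beta),
            chelator_pka=list(chelator.pka) if chelator.pka else None,
            protonation_correction=protonation_correction,
            conditional_log_beta=(
                effective_betas(chelator, ph)
                if protonation_correction
                else list(chelator.log_beta)
            ),
        )
    return meta


def _meta_hash(meta: dict) -> str:
    return hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None):
    """Write a CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if meta is not None:
            meta = dict(meta)
            meta["config_hash"] = _meta_hash(meta)
            for key, value in meta.items():
                fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


def write_json(obj: dict, path: str | Path, meta: dict | None = None):
    """Write a JSON report, embedding the metadata under ``"meta"``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta is not None:
        meta = dict(meta)
        meta["config_hash"] = _meta_hash(meta)
        payload["meta"] = meta
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")


def read_two_column_table(path: str | Path, col_x: str, col_y: str):
    """Read a delimited two-column table (header row required).

    Accepts comma-, tab-, or semicolon-delimited text and '#' comment
    lines; returns the two named columns as float arrays.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in (col_x, col_y):
        if col not in df.columns:
            raise ConfigError(
                f"{path}: expected column {col!r}, found {list(df.columns)}"
            )
    return df[col_x].to_numpy(float), df[col_y].to_numpy(float)


def speciation_table(state: SpeciationState) -> pd.DataFrame:
    """One row per species: concentration and fraction of its pool.

    Transferrin species are fractions of total transferrin; free iron
    and complexes are fractions of total iron; free ligand of total
    ligand.
    """
    fe_pool = state.fe_total
    tf_pool = state.tf_total
    lig_pool = state.ligand_total
    rows = []

    def frac(conc, pool):
        return conc / pool if pool > 0 else float("nan")

    rows.append(("free_fe", state.free_fe, frac(state.free_fe, fe_pool)))
    rows.append(("tf_apo", state.tf0, frac(state.tf0, tf_pool)))
    rows.append(("tf_mono", state.tf1, frac(state.tf1, tf_pool)))
    rows.append(("tf_holo", state.tf2, frac(state.tf2, tf_pool)))
    rows.append(
        ("free_ligand", state.free_ligand, frac(state.free_ligand, lig_pool))
    )
    for i, c in enumerate(state.complexes, start=1):
        rows.append((f"fe_l{i}", c, frac(c, fe_pool)))
    return pd.DataFrame(
        rows, columns=["species", "concentration_mol_per_l", "fraction_of_pool"]
    )
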