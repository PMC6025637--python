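"""End-to-end family analysis pipeline and activity summaries.

``run_pipeline`` executes the stages in order — ingest, annotate, type and
deduplicate, physicochemistry, align, distances, tree with bootstrap,
diagnostic-residue groups, conservation profiles, and (when structures are
given) dipoles plus electrostatic clades — and writes versioned TSV / JSON /
Newick artifacts.  The pipeline is a pure function of (inputs, config,
seed): artifacts carry the configuration hash instead of timestamps, so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .align import align_progressive
from .distance import (
    distance_matrix,
    distances_long_table,
    group_divergence,
    write_phylip,
)
from .electrostatics import cluster_clades, fragment_dipole, read_pqr
from .errors import PipelineError
from .physchem import BJELLQVIST, physchem_profile
from .profiling import (
    check_hotspots,
    classify_group,
    column_profile,
    count_region_variants,
    default_group_rules,
    load_group_rules,
    profile_table,
)
from .substitution import jtt_model
from .tree import bootstrap_support

__all__ = [
    "PipelineConfig",
    "ActivityRecord",
    "load_activity_table",
    "packaged_activity_table",
    "summarize_activity_by_group",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Serializable pipeline settings; echoed verbatim into every report."""

    input_fasta: str = ""
    input_kind: str = "cdna"  # 'cdna' | 'protein-precursor' | 'protein-mature'
    output_dir: str = "actinofam_out"
    alpha: float = 1.7014
    n_categories: int = 8
    bootstrap_replicates: int = 200
    gap_policy: str = "complete"
    signal_len: int = 19
    search_window: int = 45
    min_protein_len: int = 50
    reference_id: str | None = None
    rule_table: str | None = None  # None -> packaged rules
    nterm_region: tuple[int, int] = (1, 27)
    seed: int = 0
    pqr_dir: str | None = None
    grid_spacing: float = 1.0
    skin: tuple[float, float] = (3.0, 7.0)
    dielectric: float = 80.0
    screening_length: float | None = None
    dipole_fragment: tuple[int, int] = (1, 27)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("nterm_region", "skin", "dipole_fragment"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)

    def hash(self) -> str:
        """Hash of every setting that can influence results (the output
        location itself is excluded, so moving a run does not change it)."""
        d = asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ActivityRecord:
    isoform_id: str
    hu_per_mg: float
    source: str = ""
    clade: str | None = None

    def __post_init__(self) -> None:
        if self.hu_per_mg <= 0:
            raise ValueError(f"{self.isoform_id}: activity must be positive")


def load_activity_table(path) -> list[ActivityRecord]:
    """Read an activity annotation TSV (id, clade, hu_per_mg, source)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        clade = row.get("clade")
        if isinstance(clade, float) and np.isnan(clade):
            clade = None
        records.append(
            ActivityRecord(
                isoform_id=str(row["id"]),
                hu_per_mg=float(row["hu_per_mg"]),
                source=str(row.get("source", "")),
                clade=clade or None,
            )
        )
    return records


def packaged_activity_table() -> list[ActivityRecord]:
    """The packaged hemolytic-activity annotations of the family's
    recombinant members (HU per mg, with their electrostatic clades)."""
    with resources.as_file(
        resources.files("actinofam.data").joinpath("activity_hcrispa.tsv")
    ) as p:
        return load_activity_table(p)


def summarize_activity_by_group(
    activities: list[ActivityRecord],
    assignments: dict[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group geometric mean activity and pairwise fold-ratio matrix.

    ``assignments`` maps isoform id -> group label; records whose clade is
    already annotated are used directly when no assignment is given.  Groups
    with no usable members are omitted (activity must be positive, so the
    geometric mean is well-defined).
    """
    groups: dict[str, list[float]] = {}
    for rec in activities:
        label = (assignments or {}).get(rec.isoform_id, rec.clade)
        if label:
            groups.setdefault(label, []).append(rec.hu_per_mg)
    if not groups:
        raise PipelineError("no activity record carries a group label")
    geo = pd.Series(
        {g: float(np.exp(np.mean(np.log(v)))) for g, v in sorted(groups.items())},
        name="geometric_mean_hu_per_mg",
    )
    ratio = pd.DataFrame(
        geo.values[:, None] / geo.values[None, :], index=geo.index, columns=geo.index
    )
    return geo, ratio


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict and
    writes artifacts under ``config.output_dir``.

    Stage failures raise :class:`PipelineError` carrying the stage name and
    the offending record.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log: list[str] = [f"config {chash}", f"seed {config.seed}"]
    bundle: dict = {"config_hash": chash}

    def stage(name: str):
        def deco(fn):
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.append(f"stage {name}: ok")
            return result

        return deco

    @stage("ingest")
    def matures():
        if not config.input_fasta or not Path(config.input_fasta).exists():
            raise PipelineError(
                f"stage 'ingest' failed: input FASTA {config.input_fasta!r} not found"
            )
        if config.input_kind == "cdna":
            records = fio.read_fasta(config.input_fasta, alphabet="dna")
            precursors = []
            for rec in records:
                orfs = fio.find_orfs(rec, min_protein_len=config.min_protein_len)
                if not orfs:
                    raise PipelineError(
                        f"stage 'ingest' failed: no ORF of >= {config.min_protein_len} aa "
                        f"in record {rec.id!r}"
                    )
                protein = fio.translate_orf(rec, orfs[0])
                precursors.append((rec.id, protein))
        else:
            records = fio.read_fasta(config.input_fasta, alphabet="protein")
            precursors = [(r.id, r.sequence) for r in records]
        if config.input_kind == "protein-mature":
            return precursors
        annotated = []
        for rid, protein in precursors:
            ann = fio.annotate_precursor(
                protein, signal_len=config.signal_len, search_window=config.search_window
            )
            annotated.append((rid, ann.mature))
        return annotated

    @stage("deduplicate")
    def isoforms():
        return fio.deduplicate(matures)

    iso_df = fio.isoform_report(isoforms)
    _write_tsv(iso_df, out / "isoforms.tsv", chash)
    bundle["isoforms"] = iso_df

    @stage("physchem")
    def physchem_df():
        rows = []
        for iso in isoforms:
            prof = physchem_profile(iso.id, iso.sequence, BJELLQVIST)
            rows.append(
                {
                    "id": prof.id,
                    "length": prof.length,
                    "mass_kDa": round(prof.average_mass_da / 1000.0, 2),
                    "pI": round(prof.pi, 2),
                    "charge_pH7.4": round(prof.net_charge_at[7.4], 2),
                    "pka_table": prof.pka_table,
                }
            )
        return pd.DataFrame(rows)

    _write_tsv(physchem_df, out / "physchem.tsv", chash)
    bundle["physchem"] = physchem_df

    @stage("align")
    def msa():
        if len(isoforms) < 2:
            raise PipelineError(
                "stage 'align' failed: fewer than two distinct isoforms"
            )
        return align_progressive(
            [(iso.id, iso.sequence) for iso in isoforms],
            reference_id=config.reference_id,
        )

    model = jtt_model(gamma_shape=config.alpha, n_categories=config.n_categories)

    @stage("distances")
    def dmat():
        return distance_matrix(msa, model, gap_policy=config.gap_policy)

    write_phylip(dmat, out / "distances.phylip")
    _write_tsv(distances_long_table(dmat), out / "distances.tsv", chash)
    bundle["distances"] = dmat

    @stage("groups")
    def assignments():
        rules = (
            load_group_rules(config.rule_table)
            if config.rule_table
            else default_group_rules()
        )
        return {
            iso.id: classify_group(iso.id, msa.row(iso.id), msa, rules)
            for iso in isoforms
        }

    group_df = pd.DataFrame(
        [{"id": k, "group": v.label} for k, v in assignments.items()]
    )
    _write_tsv(group_df, out / "groups.tsv", chash)
    bundle["groups"] = {k: v.label for k, v in assignments.items()}

    @stage("divergence")
    def divergence():
        labels = {k: v.label for k, v in assignments.items()}
        return group_divergence(dmat, labels)

    bundle["divergence"] = divergence

    @stage("tree")
    def tree():
        return bootstrap_support(
            msa,
            model,
            replicates=config.bootstrap_replicates,
            seed=np.random.default_rng(config.seed),
            gap_policy=config.gap_policy,
        )

    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    bundle["tree"] = tree

    @stage("profiles")
    def profiles():
        profs = column_profile(msa)
        table = profile_table(profs)
        variants = {
            t: count_region_variants(msa, region=config.nterm_region, n_type=t)
            for t in ("A", "S")
        }
        hotspots = pd.DataFrame(
            [check_hotspots(iso.id, msa.row(iso.id), msa) for iso in isoforms]
        )
        return table, variants, hotspots

    logo_table, variants, hotspot_df = profiles
    _write_tsv(logo_table, out / "logo.tsv", chash)
    _write_tsv(hotspot_df, out / "hotspots.tsv", chash)
    bundle["region_variants"] = variants
    bundle["hotspots"] = hotspot_df

    if config.pqr_dir:

        @stage("electrostatics")
        def electro():
            paths = sorted(Path(config.pqr_dir).glob("*.pqr"))
            if not paths:
                raise PipelineError(
                    f"stage 'electrostatics' failed: no PQR files in {config.pqr_dir!r}"
                )
            structures = [read_pqr(p) for p in paths]
            dip_rows = []
            for s in structures:
                d = fragment_dipole(s, fragment=config.dipole_fragment)
                dip_rows.append(
                    {
                        "id": s.id,
                        "dipole_debye": d.magnitude_debye,
                        "dx": d.direction[0] if d.direction is not None else np.nan,
                        "dy": d.direction[1] if d.direction is not None else np.nan,
                        "dz": d.direction[2] if d.direction is not None else np.nan,
                        "net_charge_e": d.net_charge,
                    }
                )
            clades = None
            if len(structures) >= 3:
                clades = cluster_clades(
                    structures,
                    k=3,
                    spacing=config.grid_spacing,
                    skin=config.skin,
                    dielectric=config.dielectric,
                    screening_length=config.screening_length,
                )
            return pd.DataFrame(dip_rows), clades

        dip_df, clades = electro
        _write_tsv(dip_df, out / "dipoles.tsv", chash)
        bundle["dipoles"] = dip_df
        if clades is not None:
            _write_tsv(
                clades.similarity.reset_index().rename(columns={"index": "id"}),
                out / "similarity.tsv",
                chash,
            )
            clade_df = pd.DataFrame(
                [{"id": k, "clade": v} for k, v in sorted(clades.labels.items())]
            )
            _write_tsv(clade_df, out / "clades.tsv", chash)
            bundle["clades"] = clades.labels

    (out / "config.json").write_text(config.to_json() + "\n")
    summary = {
        "config_hash": chash,
        "n_input": len(matures),
        "n_isoforms": len(isoforms),
        "n_A": sum(1 for i in isoforms if i.n_type == "A"),
        "n_S": sum(1 for i in isoforms if i.n_type == "S"),
        "mean_pairwise_distance": float(np.mean(dmat.condensed())),
        "region_variants": variants,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log) + "\n")
    bundle["summary"] = summary
    return bundle
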