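"""End-to-end orchestration: files in, result bundle + manifest out.

Each stage wraps the corresponding library call; any stage failure is
re-raised as :class:`PipelineError` naming the stage.  All randomness flows
from the single configured seed, split per stage by stable stage names, so
stage order cannot change results and identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata as importlib_metadata
from pathlib import Path

import pandas as pd
import yaml

from . import community, io, isotopes, occurrence, polygon
from .datatypes import RunConfig, stage_seed
from .mixing import IsotopeMixingModel

MARKER_PHYLA = {"arthropod_COI": "Arthropoda", "plant_ITS2": "Streptophyta"}
BAIT_GENERA = {"plant_ITS2": ("Arachis", "Avena"), "arthropod_COI": ()}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, err: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def _version() -> str:
    try:
        return importlib_metadata.version("omnidiet")
    except importlib_metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def config_hash(config: RunConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@_stage("occurrence")
def occurrence_track(
    table, meta: pd.DataFrame, config: RunConfig, out: Path, tag: str
) -> occurrence.OccurrenceMatrix:
    filtered = occurrence.filter_asv_table(
        table,
        target_phylum=MARKER_PHYLA[table.marker],
        excluded_genera=BAIT_GENERA[table.marker],
    )
    rra, zero = occurrence.relative_read_abundance(filtered)
    occ = occurrence.occurrence_from_rra(
        rra, config.rra_presence_threshold, zero_total_samples=zero
    )
    # genus-level taxonomy echo for the summary tables
    foo = occurrence.foo_summary(occ, filtered.taxonomy)
    occ.presence.rename_axis("sample_id").to_csv(out / f"{tag}_occurrence.csv")
    foo.rename_axis("taxon").to_csv(out / f"{tag}_foo.csv")
    for factor in ("habitat", "session"):
        per = occurrence.per_group_foo(occ, meta, factor)
        wide = pd.DataFrame({lvl: df["foo_percent"] for lvl, df in per.items()})
        wide.rename_axis("taxon").to_csv(out / f"{tag}_foo_by_{factor}.csv")
    return occ


@_stage("community")
def community_track(
    occ, meta: pd.DataFrame, config: RunConfig, out: Path, tag: str
) -> None:
    dm = community.sorensen_matrix(occ)
    ord_res = community.pcoa(dm)
    ord_res.as_frame(2).rename_axis("sample_id").to_csv(out / f"{tag}_pcoa.csv")
    perm = community.permanova_two_way(
        dm, meta, ("habitat", "session"),
        n_perm=config.n_permutations,
        seed=stage_seed(config.seed, f"permanova:{tag}"),
    )
    perm.table.to_csv(out / f"{tag}_permanova.csv")
    for factor in ("habitat", "session"):
        disp = community.permdisp(
            dm, meta[factor],
            n_perm=config.n_permutations,
            seed=stage_seed(config.seed, f"permdisp:{tag}:{factor}"),
        )
        pd.DataFrame(
            {
                "mean_distance_to_centroid": disp.group_means,
                "F": disp.F,
                "df1": disp.df1,
                "df2": disp.df2,
                "p_perm": disp.p_perm,
            }
        ).rename_axis("group").to_csv(out / f"{tag}_permdisp_{factor}.csv")


@_stage("sources")
def source_track(
    isotope_records: pd.DataFrame, config: RunConfig, out: Path,
    a_priori_groups: dict[str, list[str]] | None = None,
) -> isotopes.SourceGroupSet:
    src = isotope_records[isotope_records["role"] == "source"]
    a_priori_groups = a_priori_groups or {}
    fixed_taxa = {t for m in a_priori_groups.values() for t in m}
    to_cluster = src[~src["label"].isin(fixed_taxa)]
    n_taxa = to_cluster["label"].nunique()
    if n_taxa >= 2:
        clustered = isotopes.ward_cluster_sources(
            to_cluster, k_range=(2, min(8, n_taxa))
        )
    else:
        clustered = isotopes.SourceGroupSet(
            groups={t: [t] for t in to_cluster["label"].unique()}
        )
    sources = isotopes.build_source_design(
        clustered, a_priori_groups, isotope_records
    )
    sources.stats.to_csv(out / "source_groups.csv")
    return sources


@_stage("polygon")
def polygon_track(
    sources, isotope_records: pd.DataFrame, config: RunConfig, out: Path
) -> list:
    consumers = isotope_records[isotope_records["role"] == "consumer"].set_index(
        "specimen_id"
    )
    report = polygon.simulate_mixing_region(
        sources, config.dtdf, consumers,
        n_iter=config.polygon_iterations,
        seed=stage_seed(config.seed, "polygon"),
    )
    report.as_frame().to_csv(out / "polygon_report.csv")
    return polygon.flag_outliers(report)


@_stage("mixing-model")
def mixing_track(
    sources, isotope_records: pd.DataFrame, meta: pd.DataFrame,
    config: RunConfig, out: Path, excluded: list,
) -> dict:
    config.check_aggregation(sorted(sources.names))
    model = IsotopeMixingModel.from_frames(
        isotope_records, sources, config.dtdf,
        metadata=meta, factors=("habitat", "session"),
        exclude=tuple(excluded), alpha=config.dirichlet_alpha,
    )
    results = model.fit(config.mcmc, seed=stage_seed(config.seed, "mix"))
    summary = results.summary(by="habitat")
    summary.to_csv(out / "posterior_summary.csv", index=False)
    if config.aggregation_map:
        results.summary(aggregation_map=config.aggregation_map).to_csv(
            out / "posterior_summary_aggregated.csv", index=False
        )
    vp = results.variance_partition()
    vp.to_csv(out / "variance_partition.csv")
    diag = results.diagnostics()
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)
    return diag


def run_pipeline(
    config: RunConfig,
    paths: dict[str, str | Path],
    out_dir: str | Path,
    a_priori_groups: dict[str, list[str]] | None = None,
) -> dict:
    """Run every applicable stage and write the result bundle.

    ``paths`` may contain ``arthropod_asv``, ``plant_asv``, ``metadata`` and
    ``isotopes``; tracks whose inputs are absent are skipped.  Returns the
    run manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = io.read_metadata(paths["metadata"]) if "metadata" in paths else None
    for marker, key, tag in (
        ("arthropod_COI", "arthropod_asv", "arthropod"),
        ("plant_ITS2", "plant_asv", "plant"),
    ):
        if key not in paths:
            continue
        table = io.read_asv_table(paths[key], marker)
        occ = occurrence_track(table, meta, config, out, tag)
        if meta is not None:
            community_track(occ, meta, config, out, tag)
    diag = None
    if "isotopes" in paths:
        records = io.read_isotopes(paths["isotopes"])
        sources = source_track(records, config, out, a_priori_groups)
        excluded = polygon_track(sources, records, config, out)
        if meta is not None:
            diag = mixing_track(sources, records, meta, config, out, excluded)
    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "version": _version(),
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "mixing_diagnostics": diag,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
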