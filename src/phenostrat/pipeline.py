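"""End-to-end orchestration from a single validated config.

``run_pipeline`` executes the stages in dependency order — tag notes,
build BM25 vectors, cluster, then the independent analysis stages
(stability, symptom groups, enrichment, comorbidity, dysregulation) —
writing every stage output in its canonical format plus a machine-readable
run manifest. Stage parameters, input paths and seeds all live in a
schema-validated RunConfig (unknown keys are rejected); analysis-stage
failures are logged and recorded in the manifest rather than aborting,
while failures in the mandatory spine abort the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .containers import ConfigurationError, Partition
from .synthetic_cohort import CohortConfig, generate_cohort, read_notes, write_cohort
from .dictionary_ner import read_blocklist, read_dictionary, tag_corpus
from .phenotype_vectors import BM25Params, vectorize
from .patient_clustering import cluster_patients, write_edge_list
from .cluster_stability import stability_curve
from .symptom_grouping import symptom_profiles, ward_groups
from .enrichment_stats import (
    metadata_contrasts,
    patient_strata,
    prescription_enrichment,
    stratified_binomial_enrichment,
)
from .comorbidity_networks import (
    pair_cooccurrence,
    pair_directionality,
    top_pairs_by_unique_codes,
)
from .dysregulation import BocpdConfig, dysregulation_profiles, lab_contrasts
from .synthetic_cohort import HBA1C_TEST_ID

logger = logging.getLogger("phenostrat")

ALL_STAGES = (
    "tag", "vectorize", "cluster", "stability", "symptom_groups",
    "enrich", "comorbidity", "dysreg",
)
MANDATORY_STAGES = ("tag", "vectorize", "cluster")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputPaths(_Strict):
    notes: str
    diagnoses: str
    patients: str
    labs: str
    prescriptions: str
    dictionaries: list[str]
    blocklist: str | None = None


class ClusteringParams(_Strict):
    cosine_cutoff: float = 0.5
    inflation: float = 1.2
    min_cluster: int = 11
    analysis_min: int = 50
    bm25_b: float = 0.75
    bm25_k1: float = 1.2


class StabilityParams(_Strict):
    mode: str = "dilute"
    alphas: list[float] = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    replicates: int = 5


class EnrichmentParams(_Strict):
    min_support: int = 10
    alpha: float = 0.05
    atc_level: int = 3


class ComorbidityParams(_Strict):
    alpha: float = 0.01
    smoothing: float = 1.0
    max_unique_codes: int = 100
    min_carriers: int = 5


class DysregulationParams(_Strict):
    threshold: float = 53.0
    min_criteria: int = 3
    lab_coverage: float = 0.75


class RunConfig(_Strict):
    """Schema-validated pipeline configuration."""

    inputs: InputPaths | None = None
    simulate: dict | None = None  # CohortConfig overrides; mutually exclusive
    stages: list[str] = list(ALL_STAGES)
    clustering: ClusteringParams = ClusteringParams()
    stability: StabilityParams = StabilityParams()
    enrichment: EnrichmentParams = EnrichmentParams()
    comorbidity: ComorbidityParams = ComorbidityParams()
    dysregulation: DysregulationParams = DysregulationParams()
    hba1c_test_id: str = HBA1C_TEST_ID
    seed: int = 0
    outdir: str = "phenostrat_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(cfg: RunConfig) -> dict:
    if (cfg.inputs is None) == (cfg.simulate is None):
        raise ConfigurationError("exactly one of 'inputs' or 'simulate' is required")
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        cohort = generate_cohort(CohortConfig(**sim))
        from .dictionary_ner import entries_from_frame

        return {
            "notes": cohort.notes,
            "diagnoses": cohort.diagnoses,
            "patients": cohort.patients,
            "labs": cohort.labs,
            "prescriptions": cohort.prescriptions,
            "dictionaries": entries_from_frame(cohort.icd10_dictionary)
            + entries_from_frame(cohort.custom_dictionary),
            "blocklist": None,
            "cohort": cohort,
        }
    paths = cfg.inputs
    for name in ("notes", "diagnoses", "patients", "labs", "prescriptions"):
        p = getattr(paths, name)
        if not Path(p).exists():
            raise ConfigurationError(f"input file for {name!r} not found: {p}")
    entries = []
    for d in paths.dictionaries:
        if not Path(d).exists():
            raise ConfigurationError(f"dictionary not found: {d}")
        entries.extend(read_dictionary(d))
    diagnoses = pd.read_csv(paths.diagnoses, sep="\t", parse_dates=["date"])
    if "source" not in diagnoses.columns:
        diagnoses["source"] = "assigned"
    return {
        "notes": read_notes(paths.notes),
        "diagnoses": diagnoses,
        "patients": pd.read_csv(
            paths.patients, sep="\t", parse_dates=["birth_date", "onset_date"]
        ),
        "labs": pd.read_csv(paths.labs, sep="\t", parse_dates=["date"]),
        "prescriptions": pd.read_csv(paths.prescriptions, sep="\t", parse_dates=["date"]),
        "dictionaries": entries,
        "blocklist": read_blocklist(paths.blocklist) if paths.blocklist else None,
        "cohort": None,
    }


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df2 = df.copy()
    for col in df2.columns:
        if pd.api.types.is_datetime64_any_dtype(df2[col]):
            df2[col] = df2[col].dt.strftime("%Y-%m-%d")
    df2.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = _load_inputs(config)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "outputs": {},
    }
    if data["cohort"] is not None:
        write_cohort(data["cohort"], out / "cohort")
        manifest["outputs"]["cohort"] = str(out / "cohort")

    def record(stage, **info):
        manifest["stages"][stage] = {"status": "ok", **info}

    events = data["diagnoses"]
    mentions = None
    if "tag" in config.stages:
        mentions, mined = tag_corpus(
            data["notes"], data["dictionaries"], blocklist=data["blocklist"]
        )
        events = pd.concat([data["diagnoses"], mined], ignore_index=True)
        _write_tsv(mentions, out / "mentions.tsv")
        _write_tsv(events, out / "events.tsv")
        record("tag", n_mentions=len(mentions), n_events=len(events))

    vectors = stats = None
    if "vectorize" in config.stages:
        params = BM25Params(b=config.clustering.bm25_b, k1=config.clustering.bm25_k1)
        vectors, stats, empty = vectorize(events, params)
        _write_tsv(vectors.to_frame(), out / "vectors.tsv")
        with open(out / "corpus_stats.json", "w") as fh:
            json.dump(
                {
                    "n_patients": stats.n_patients,
                    "mean_length": stats.mean_length,
                    "code_counts": stats.code_counts.to_dict(),
                },
                fh, sort_keys=True, indent=1,
            )
        record("vectorize", n_patients=len(vectors), n_codes=len(vectors.codes),
               n_empty=len(empty))

    partition = network = None
    if "cluster" in config.stages:
        if vectors is None:
            raise ConfigurationError("cluster stage requires vectorize")
        partition, network = cluster_patients(
            vectors,
            cutoff=config.clustering.cosine_cutoff,
            inflation=config.clustering.inflation,
        )
        _write_tsv(partition.to_frame(), out / "partition.tsv")
        write_edge_list(network, out / "edges.tsv")
        retained = partition.retained(config.clustering.min_cluster)
        record(
            "cluster",
            n_clusters=partition.n_clusters(),
            n_retained_clusters=retained.n_clusters(),
            n_patients_clustered=len(partition),
            n_patients_retained=len(retained),
        )

    def optional(stage, fn):
        if stage not in config.stages:
            return
        if partition is None:
            raise ConfigurationError(f"{stage} stage requires cluster")
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - optional stage, recorded
            logger.exception("stage %s failed", stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    def _stability():
        curve = stability_curve(
            partition, network, config.stability.alphas,
            mode=config.stability.mode, replicates=config.stability.replicates,
            seed=config.seed, inflation=config.clustering.inflation,
        )
        curve.to_tsv(out / "stability.tsv")
        record("stability", reference_lines=curve.reference_lines,
               mean_vi=curve.mean_by_alpha().to_dict())

    def _symptom_groups():
        analysis = partition.analysis(config.clustering.analysis_min)
        profiles = symptom_profiles(analysis, events)
        k = min(7, len(profiles))
        grouping = ward_groups(profiles, k=k)
        profiles.to_csv(out / "symptom_profiles.tsv", sep="\t")
        _write_tsv(grouping.to_frame(), out / "symptom_groups.tsv")
        (out / "symptom_dendrogram.nwk").write_text(grouping.newick() + "\n")
        record("symptom_groups", k=k, groups=grouping.groups)

    def _enrich():
        strata = patient_strata(data["patients"])
        enr = stratified_binomial_enrichment(
            partition.retained(config.clustering.min_cluster), events, strata,
            min_support=config.enrichment.min_support, alpha=config.enrichment.alpha,
        )
        _write_tsv(enr, out / "enrichment_codes.tsv")
        meta = data["patients"].copy()
        # reference date for age/duration: latest event date in the corpus
        end = pd.to_datetime(events["date"]).max()
        meta["age_years"] = (end - meta["birth_date"]).dt.days / 365.25
        meta["diabetes_duration_years"] = (end - meta["onset_date"]).dt.days / 365.25
        contrasts = metadata_contrasts(
            partition.retained(config.clustering.min_cluster),
            meta[["patient_id", "age_years", "diabetes_duration_years"]],
            alpha=config.enrichment.alpha,
        )
        _write_tsv(contrasts, out / "enrichment_metadata.tsv")
        rx = prescription_enrichment(
            partition, data["prescriptions"], level=config.enrichment.atc_level,
            min_cluster=config.clustering.analysis_min, alpha=config.enrichment.alpha,
        )
        _write_tsv(rx, out / "enrichment_prescriptions.tsv")
        record("enrich", n_code_tests=len(enr),
               n_significant_codes=int(enr["significant"].sum()) if len(enr) else 0,
               n_significant_prescriptions=int(rx["significant"].sum()) if len(rx) else 0)

    def _comorbidity():
        pairs = pair_cooccurrence(
            events, smoothing=config.comorbidity.smoothing,
            alpha=config.comorbidity.alpha,
            min_carriers=config.comorbidity.min_carriers,
        )
        sig = pairs[pairs["significant"]]
        top = top_pairs_by_unique_codes(sig, config.comorbidity.max_unique_codes)
        direction = pair_directionality(
            events, pairs=top if len(top) else None, alpha=config.comorbidity.alpha
        )
        _write_tsv(pairs, out / "comorbidity_pairs.tsv")
        _write_tsv(direction, out / "comorbidity_directionality.tsv")
        record("comorbidity", n_pairs=len(pairs), n_significant=int(len(sig)),
               n_directional=int(direction["directional"].sum()) if len(direction) else 0)

    def _dysreg():
        hba1c = data["labs"].loc[
            data["labs"]["test_id"] == config.hba1c_test_id,
            ["patient_id", "date", "value"],
        ]
        onsets = data["patients"].set_index("patient_id")["onset_date"]
        profiles = dysregulation_profiles(
            events, hba1c, onsets, BocpdConfig(),
            min_criteria=config.dysregulation.min_criteria,
        )
        _write_tsv(profiles.reset_index(), out / "dysregulation.tsv")
        general_labs = data["labs"].loc[data["labs"]["test_id"] != config.hba1c_test_id]
        groups = profiles["dysregulated"].map({True: "dysregulated", False: "regulated"})
        contrasts = lab_contrasts(
            general_labs, groups, coverage=config.dysregulation.lab_coverage
        )
        _write_tsv(contrasts["ks"], out / "lab_contrasts.tsv")
        record(
            "dysreg",
            score_counts={int(k): int(v) for k, v in
                          profiles["score"].value_counts().sort_index().items()},
            n_dysregulated=int(profiles["dysregulated"].sum()),
            manova_p=None if pd.isna(contrasts["manova_p"]) else contrasts["manova_p"],
        )

    optional("stability", _stability)
    optional("symptom_groups", _symptom_groups)
    optional("enrich", _enrich)
    optional("comorbidity", _comorbidity)
    optional("dysreg", _dysreg)

    manifest["outputs"].update(
        {p.name: str(p) for p in sorted(out.glob("*.tsv")) }
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    return manifest
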