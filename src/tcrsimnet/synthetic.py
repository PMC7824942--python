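"""Synthetic multi-sample repertoires with planted, recoverable structure.

Generates per-sample contig tables (10x CSV or AIRR TSV dialects) with
known ground truth: planted expanded clones, planted similarity clusters
(seed variants within a fixed substitution radius) and planted CDR3beta
motifs.  Background sequences are rejection-sampled so that their
similarity to every planted sequence stays below the design threshold
minus a safety margin, which makes cluster recovery deterministic.

Background CDR3s are random strings with fixed C...F termini rather than
realistic V(D)J products; realism is a non-goal, edit-distance structure
is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tcrsimnet.similarity import lsim

AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    pass


@dataclass
class PlantedCluster:
    """A seed alpha/beta pair plus variants within a substitution radius."""

    cdr3a_seed: str
    cdr3b_seed: str
    n_variants: int
    radius: int = 2
    samples: list[str] = field(default_factory=list)  # cycled over variants
    clone_size: int = 2


@dataclass
class PlantedMotif:
    motif: str
    carriers: int
    samples: list[str] = field(default_factory=list)
    clone_size: int = 2


@dataclass
class SimulationConfig:
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 2, "AD": 2, "MCI": 2}
    )
    cells_per_sample: int = 60
    min_cdr3_length: int = 10
    max_cdr3_length: int = 18
    clone_size_geom_p: float = 0.5
    tau: float = 0.8
    margin: float = 0.1
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    ambiguous_rate: float = 0.05
    nonproductive_rate: float = 0.05
    trim: int = 2
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{group}{i + 1}"
            for group, n in self.samples_per_group.items()
            for i in range(n)
        ]

    @property
    def group_by_sample(self) -> dict[str, str]:
        return {
            f"{group}{i + 1}": group
            for group, n in self.samples_per_group.items()
            for i in range(n)
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        clusters = [PlantedCluster(**c) for c in raw.pop("planted_clusters", [])]
        motifs = [PlantedMotif(**m) for m in raw.pop("planted_motifs", [])]
        return cls(planted_clusters=clusters, planted_motifs=motifs, **raw)


@dataclass
class GroundTruth:
    """What was planted, keyed by (sample_id, cdr3a, cdr3b) clonotype identity."""

    cell_clones: dict[tuple[str, str], tuple] = field(default_factory=dict)
    cluster_members: list[list[tuple[str, str, str]]] = field(default_factory=list)
    motif_carriers: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    seed: int = 0


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    interior = "".join(AA[i] for i in rng.integers(0, len(AA), length - 2))
    return "C" + interior + "F"


def _mutate_interior(rng: np.random.Generator, seq: str, k: int) -> str:
    """Apply k substitutions at distinct interior positions (termini fixed)."""
    positions = rng.choice(np.arange(1, len(seq) - 1), size=k, replace=False)
    chars = list(seq)
    for p in positions:
        current = chars[p]
        choices = [c for c in AA if c != current]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def _validate_cluster(cfg: SimulationConfig, cluster: PlantedCluster) -> None:
    concat_len = len(cluster.cdr3a_seed) + len(cluster.cdr3b_seed)
    worst = 1.0 - 2.0 * cluster.radius / concat_len
    if worst <= cfg.tau:
        raise ConfigError(
            f"cluster seed {cluster.cdr3b_seed}: radius {cluster.radius} cannot "
            f"guarantee pairwise L-sim > {cfg.tau} at concat length {concat_len}"
        )
    if cluster.clone_size < 2:
        raise ConfigError("planted cluster clone_size must be >= 2 (must survive clonal filter)")


def _validate_motif(cfg: SimulationConfig, motif: PlantedMotif) -> None:
    interior = cfg.max_cdr3_length - 2 * cfg.trim - 2  # minus fixed termini
    if len(motif.motif) > interior:
        raise ConfigError(
            f"motif {motif.motif!r} (len {len(motif.motif)}) exceeds the usable "
            f"CDR3beta interior ({interior}) at max length {cfg.max_cdr3_length}"
        )
    if motif.clone_size < 2:
        raise ConfigError("planted motif clone_size must be >= 2")


def _far_from_all(seq: str, avoid: list[str], cutoff: float) -> bool:
    return all(lsim(seq, other) < cutoff for other in avoid)


def generate_repertoire(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Generate per-sample contig tables, metadata, and ground truth.

    Deterministic under a fixed ``config.seed``.  Planted cluster variants
    lie within the configured substitution radius of their seed (pairwise
    similarity above tau by construction); background alpha+beta concats
    are rejection-sampled below ``tau - margin`` similarity to every
    planted sequence; planted motifs are inserted into carrier CDR3beta
    interiors and rejected from all background CDR3betas.
    """
    rng = np.random.default_rng(config.seed)
    for cluster in config.planted_clusters:
        _validate_cluster(config, cluster)
    for motif in config.planted_motifs:
        _validate_motif(config, motif)

    samples = config.sample_ids
    if not samples:
        raise ConfigError("no samples configured")
    known = set(samples)
    for item in list(config.planted_clusters) + list(config.planted_motifs):
        for s in item.samples:
            if s not in known:
                raise ConfigError(f"planted item references unknown sample {s!r}")
    cutoff = config.tau - config.margin
    motif_strings = [m.motif.upper() for m in config.planted_motifs]

    truth = GroundTruth(seed=config.seed)
    # planted clone plan: (sample_id, cdr3a, cdr3b, clone_size, corruptible)
    plan: dict[str, list[tuple[str, str, int]]] = {s: [] for s in samples}
    planted_concats: list[str] = []

    for cluster in config.planted_clusters:
        assigned = cluster.samples or samples
        members = []
        variants: set[tuple[str, str]] = set()
        attempts = 0
        while len(variants) < cluster.n_variants:
            attempts += 1
            if attempts > 10_000:
                raise ConfigError("could not generate enough distinct cluster variants")
            if not variants:
                a, b = cluster.cdr3a_seed, cluster.cdr3b_seed
            else:
                k = int(rng.integers(1, cluster.radius + 1))
                ka = int(rng.integers(0, k + 1))
                a = _mutate_interior(rng, cluster.cdr3a_seed, ka) if ka else cluster.cdr3a_seed
                b = (
                    _mutate_interior(rng, cluster.cdr3b_seed, k - ka)
                    if k - ka
                    else cluster.cdr3b_seed
                )
            if (a, b) in variants:
                continue
            if any(m in b for m in motif_strings):
                continue
            variants.add((a, b))
            sample = assigned[(len(variants) - 1) % len(assigned)]
            plan[sample].append((a, b, cluster.clone_size))
            members.append((sample, a, b))
            planted_concats.append(a + b)
        truth.cluster_members.append(members)

    # cross-cluster separation must hold or recovery is ill-posed
    flat = [m for ms in truth.cluster_members for m in ms]
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            same = any(flat[i] in ms and flat[j] in ms for ms in truth.cluster_members)
            if same:
                continue
            s = lsim(flat[i][1] + flat[i][2], flat[j][1] + flat[j][2])
            if s >= cutoff:
                raise ConfigError(
                    f"planted clusters are not separable: cross-cluster L-sim {s:.3f} "
                    f">= {cutoff:.3f}"
                )

    for motif in config.planted_motifs:
        assigned = motif.samples or samples
        needle = motif.motif.upper()
        carriers = []
        seen_b: set[str] = set()
        attempts = 0
        while len(carriers) < motif.carriers:
            attempts += 1
            if attempts > 100_000:
                raise ConfigError("could not place motif carriers away from planted clusters")
            min_len = max(config.min_cdr3_length, len(needle) + 2 * config.trim + 2)
            b = _random_cdr3(rng, min_len, max(min_len, config.max_cdr3_length))
            offset = int(
                rng.integers(config.trim + 1, len(b) - config.trim - len(needle))
            ) if len(b) - config.trim - len(needle) > config.trim + 1 else config.trim + 1
            b = b[:offset] + needle + b[offset + len(needle) :]
            a = _random_cdr3(rng, config.min_cdr3_length, config.max_cdr3_length)
            if b in seen_b:
                continue
            if not _far_from_all(a + b, planted_concats, cutoff):
                continue
            seen_b.add(b)
            sample = assigned[len(carriers) % len(assigned)]
            plan[sample].append((a, b, motif.clone_size))
            carriers.append((sample, a, b))
            planted_concats.append(a + b)
        truth.motif_carriers[needle] = carriers

    # background clones fill the remaining per-sample cell budget
    contig_rows: dict[str, list[dict]] = {s: [] for s in samples}
    for sample in samples:
        planted_cells = sum(size for _, _, size in plan[sample])
        budget = config.cells_per_sample - planted_cells
        if budget < 0:
            raise ConfigError(
                f"sample {sample}: planted cells ({planted_cells}) exceed "
                f"cells_per_sample ({config.cells_per_sample})"
            )
        keys = {(a, b) for a, b, _ in plan[sample]}
        background: list[tuple[str, str, int]] = []
        while budget > 0:
            size = min(int(rng.geometric(config.clone_size_geom_p)), budget)
            attempts = 0
            while True:
                attempts += 1
                if attempts > 100_000:
                    raise ConfigError("background rejection sampling failed to converge")
                a = _random_cdr3(rng, config.min_cdr3_length, config.max_cdr3_length)
                b = _random_cdr3(rng, config.min_cdr3_length, config.max_cdr3_length)
                if (a, b) in keys:
                    continue
                if any(m in b for m in motif_strings):
                    continue
                if not _far_from_all(a + b, planted_concats, cutoff):
                    continue
                break
            keys.add((a, b))
            background.append((a, b, size))
            budget -= size

        barcode_idx = 0
        for a, b, size, corruptible in [(*p, False) for p in plan[sample]] + [
            (*bg, True) for bg in background
        ]:
            clone_key = (sample, a, b)
            for _ in range(size):
                barcode_idx += 1
                barcode = f"{sample}-BC{barcode_idx:05d}-1"
                truth.cell_clones[(sample, barcode)] = clone_key
                rows = [
                    {"barcode": barcode, "chain": "TRA", "cdr3": a, "productive": "True",
                     "high_confidence": "True"},
                    {"barcode": barcode, "chain": "TRB", "cdr3": b, "productive": "True",
                     "high_confidence": "True"},
                ]
                if corruptible and rng.random() < config.ambiguous_rate:
                    extra_b = _random_cdr3(rng, config.min_cdr3_length, config.max_cdr3_length)
                    rows.append(
                        {"barcode": barcode, "chain": "TRB", "cdr3": extra_b,
                         "productive": "True", "high_confidence": "True"}
                    )
                if corruptible and rng.random() < config.nonproductive_rate:
                    rows.append(
                        {"barcode": barcode, "chain": "TRA", "cdr3": "None",
                         "productive": "False", "high_confidence": "True"}
                    )
                contig_rows[sample].extend(rows)

    tables = {
        s: pd.DataFrame(
            contig_rows[s],
            columns=["barcode", "chain", "cdr3", "productive", "high_confidence"],
        )
        for s in samples
    }
    metadata = pd.DataFrame(
        {"sample_id": samples, "diagnosis_group": [config.group_by_sample[s] for s in samples]}
    )
    return tables, metadata, truth


def write_dataset(
    tables: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    out_dir: str | Path,
    fmt: str = "10x",
) -> dict[str, Path]:
    """Write per-sample contig tables plus metadata.csv to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, df in tables.items():
        if fmt == "10x":
            p = out_dir / f"{sample}_contigs.csv"
            df.to_csv(p, index=False)
        elif fmt == "airr":
            p = out_dir / f"{sample}_airr.tsv"
            airr = df.rename(columns={"barcode": "cell_id", "chain": "locus", "cdr3": "junction_aa"})
            airr.to_csv(p, sep="\t", index=False)
        else:
            raise ConfigError(f"unknown output format {fmt!r}")
        paths[sample] = p
    meta_path = out_dir / "metadata.csv"
    metadata.to_csv(meta_path, index=False)
    paths["metadata"] = meta_path
    return paths


def default_config(seed: int = 0) -> SimulationConfig:
    """A config with 3 separable planted clusters and one planted motif.

    Cluster seeds use short CDR3betas (trimmed length < 9) so their shared
    substrings cannot outrank the planted length-9 motif.
    """
    return SimulationConfig(
        planted_clusters=[
            PlantedCluster("CAVSDSNYQLIWG", "CASSIRSAYEQF", n_variants=4, radius=2,
                           samples=["AD1", "AD2", "MCI1", "MCI2"]),
            PlantedCluster("CAGQTGANNLFFG", "CASRPDRGLYTF", n_variants=5, radius=2,
                           samples=["AD1", "MCI1", "AD2", "MCI2", "HC1"]),
            PlantedCluster("CILRDTGRRALTG", "CASSQEWDTQYF", n_variants=6, radius=2,
                           samples=["HC1", "HC2", "AD1", "AD2", "MCI1", "MCI2"]),
        ],
        planted_motifs=[
            PlantedMotif("SSLGQAYEQ", carriers=5, samples=["AD1", "AD2", "MCI1", "MCI2", "AD1"]),
        ],
        seed=seed,
    )


def score_recovery(
    truth: GroundTruth,
    clusters,
    motif_table: pd.DataFrame | None = None,
    clonotypes=None,
) -> dict:
    """Compare recovered clusters/motifs against the planted ground truth.

    Recovered cluster members are matched to planted members by
    (sample_id, cdr3a, cdr3b); each planted cluster is matched to the
    recovered cluster with largest overlap.  Contamination counts members
    of matched recovered clusters not planted in any cluster.
    """
    key_of = {}
    if clonotypes is not None:
        for ct in clonotypes:
            key_of[ct.clonotype_id] = (ct.sample_id, ct.cdr3a, ct.cdr3b)

    recovered: list[set] = []
    for cluster in clusters:
        members = set()
        for cid, meta in zip(cluster.members, cluster.member_meta):
            if cid in key_of:
                members.add(key_of[cid])
            elif meta:
                members.add((meta.get("samples"), meta.get("cdr3a") or None, meta.get("cdr3b")))
        recovered.append(members)

    planted_all = {m for ms in truth.cluster_members for m in ms}
    cluster_reports = []
    for planted in truth.cluster_members:
        planted_set = set(planted)
        best = max(recovered, key=lambda r: len(r & planted_set), default=set())
        overlap = len(best & planted_set)
        contamination = len(best - planted_all) if overlap else 0
        cluster_reports.append(
            {
                "planted_size": len(planted_set),
                "recovered": overlap,
                "recall": overlap / len(planted_set),
                "contamination": contamination,
            }
        )

    motif_reports = {}
    if motif_table is not None:
        for needle, carriers in truth.motif_carriers.items():
            sub = motif_table[motif_table["length"] == len(needle)].reset_index(drop=True)
            hit = sub.index[sub["motif"] == needle]
            rank = int(hit[0]) + 1 if len(hit) else None
            freq = int(sub.loc[hit[0], "frequency"]) if len(hit) else 0
            motif_reports[needle] = {
                "design_frequency": len(carriers),
                "observed_frequency": freq,
                "rank": rank,
                "frequency_error": freq - len(carriers),
            }

    recalls = [r["recall"] for r in cluster_reports]
    return {
        "clusters": cluster_reports,
        "mean_recall": float(np.mean(recalls)) if recalls else 1.0,
        "total_contamination": sum(r["contamination"] for r in cluster_reports),
        "motifs": motif_reports,
    }
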