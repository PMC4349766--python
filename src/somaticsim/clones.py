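"""Tumor heterogeneity and purity: clone trees and expected mixture signal.

Two heterogeneity models are supported. Under the clone-evolution model the
tumor starts from a founder clone whose SV/CNV events are shared by every
descendant; each descendant inherits the founder genome and adds its own
events on top. Under the cancer-stem-cell (CSC) model sub-clones descend from
independent ancestors and share no events; they are produced by independent
simulations. Mixing the clone genomes with the matched normal at chosen
fractions yields samples of any purity; this module also computes the
expected relative coverage and B-allele frequency of every reference segment
under such a mixture, the quantities a CNV caller would try to recover.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aneuploidy import AneuploidyEvent, apply_chromosome_rearrangements, set_base_ploidy
from .germline import PersonalGenome
from .model import GenomeModel
from .repeats import RepeatCatalog
from .sv import (
    DEFAULT_MECHANISM_WEIGHTS,
    SVEvent,
    log_uniform_size_dist,
    plan_events,
    realize_spec,
)

log = logging.getLogger(__name__)


class CloneError(ValueError):
    pass


@dataclass
class CloneTreeConfig:
    """Parameters of one tumor simulation / clone tree.

    ``descendant_events`` are TOTAL event counts per descendant (inherited
    events included), matching the reading of "a descendant clone with 150
    events" as 50 inherited + 100 new when the founder carries 50. Set
    ``totals`` to False for additional-count semantics.
    """

    mode: str = "clone_evolution"  # or "csc"
    ploidy: int = 2
    founder_events: int = 50
    descendant_events: tuple[int, ...] = (150, 150)
    totals: bool = True
    aneuploidy_events: int = 2
    segmental_fraction: float = 0.5
    type_weights: dict | None = None
    mechanism_weights: dict = field(default_factory=lambda: dict(DEFAULT_MECHANISM_WEIGHTS))
    sv_size_min: int = 1000
    sv_size_max: int = 1_000_000
    min_shared: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("clone_evolution", "csc"):
            raise CloneError(f"unknown heterogeneity mode {self.mode!r}")
        if self.founder_events < 0:
            raise CloneError("founder_events must be >= 0")


@dataclass
class Clone:
    clone_id: str
    parent_id: str | None
    genome: GenomeModel
    events: list[SVEvent]
    aneuploidy_log: list[AneuploidyEvent]
    personal: PersonalGenome
    seed: int = 0

    @property
    def n_events(self) -> int:
        return len(self.events)


def _size_sampler(config: CloneTreeConfig, pg: PersonalGenome):
    """SV size sampler clamped so events fit the simulated chromosomes."""
    shortest = min(len(pg.reference[c]) for c in pg.reference.names)
    max_bp = max(config.sv_size_min + 1, min(config.sv_size_max, shortest // 20))
    return log_uniform_size_dist(config.sv_size_min, max_bp)


def _run_events(clone_id, model, n_events, config, catalog, pg, rng_seed):
    rng = np.random.default_rng(rng_seed)
    specs = plan_events(
        n_events,
        type_weights=config.type_weights,
        mechanism_weights=config.mechanism_weights,
        size_dist=_size_sampler(config, pg),
        seed=int(rng.integers(2**31)),
    )
    events = []
    for i, spec in enumerate(specs):
        ev = realize_spec(
            model, spec, rng, catalog=catalog,
            event_id=f"{clone_id}.e{i:04d}", min_shared=config.min_shared,
        )
        events.append(ev)
    if len(events) != n_events:
        raise CloneError(f"requested {n_events} events but realized {len(events)}")
    return events


def simulate_founder(
    pg: PersonalGenome,
    config: CloneTreeConfig,
    catalog: RepeatCatalog | None = None,
    clone_id: str = "clone0",
) -> Clone:
    """Simulate the founder clone: base ploidy, chromosome-scale
    rearrangements, then exactly ``config.founder_events`` SV events."""
    seed = config.seed
    model = set_base_ploidy(pg, config.ploidy, seed=np.random.default_rng([seed, 1]).integers(2**31))
    model, aneu = apply_chromosome_rearrangements(
        model,
        config.aneuploidy_events,
        segmental_fraction=config.segmental_fraction,
        seed=int(np.random.default_rng([seed, 2]).integers(2**31)),
    )
    events = _run_events(clone_id, model, config.founder_events, config, catalog, pg,
                         rng_seed=[seed, 3])
    log.info("founder %s: %d SV events, %d aneuploidy events",
             clone_id, len(events), len(aneu))
    return Clone(clone_id, None, model, events, aneu, pg, seed=seed)


def derive_descendant(
    parent: Clone,
    total_events: int,
    config: CloneTreeConfig,
    catalog: RepeatCatalog | None = None,
    clone_id: str | None = None,
    salt: int = 1,
) -> Clone:
    """Derive a descendant clone sharing all of the parent's events.

    ``total_events`` counts inherited events when ``config.totals`` is True
    (the default), otherwise it is the number of additional events. New events
    are placed on the parent's already rearranged coordinates.
    """
    inherited = len(parent.events)
    if config.totals:
        n_new = total_events - inherited
        if n_new < 0:
            raise CloneError(
                f"descendant total {total_events} is below the {inherited} "
                "inherited events"
            )
    else:
        n_new = total_events
    clone_id = clone_id or f"{parent.clone_id}.d{salt}"
    model = parent.genome.clone()
    events = _run_events(clone_id, model, n_new, config, catalog, parent.personal,
                         rng_seed=[config.seed, 100 + salt])
    return Clone(
        clone_id, parent.clone_id, model, list(parent.events) + events,
        list(parent.aneuploidy_log), parent.personal, seed=config.seed,
    )


def simulate_clone_tree(
    pg: PersonalGenome,
    config: CloneTreeConfig,
    catalog: RepeatCatalog | None = None,
) -> list[Clone]:
    """Founder plus one descendant per entry of ``config.descendant_events``."""
    founder = simulate_founder(pg, config, catalog, clone_id="clone0")
    clones = [founder]
    for i, total in enumerate(config.descendant_events, start=1):
        clones.append(
            derive_descendant(founder, total, config, catalog,
                              clone_id=f"clone{i}", salt=i)
        )
    return clones


def simulate_csc(
    pg: PersonalGenome,
    configs: list[CloneTreeConfig],
    catalog: RepeatCatalog | None = None,
) -> list[Clone]:
    """Independent ancestor clones (cancer-stem-cell model): no shared events."""
    if not configs:
        raise CloneError("at least one configuration required")
    seeds = [c.seed for c in configs]
    if len(set(seeds)) != len(seeds):
        log.warning("duplicate seeds across CSC clones: %s", seeds)
    return [
        simulate_founder(pg, cfg, catalog, clone_id=f"clone{i}")
        for i, cfg in enumerate(configs)
    ]


# -- purity / mixture math ----------------------------------------------------


@dataclass
class MixtureManifest:
    """Recipe for read-level mixing plus the expected segment-level signal.

    ``components`` is a list of (component_id, fasta_path_or_None, fraction)
    covering the tumor clones and the normal; fractions sum to 1 and the tumor
    fractions sum to the purity. ``signal`` is a per-segment table of expected
    relative coverage and expected BAF at phased het loci.
    """

    components: list[tuple[str, str | None, float]]
    purity: float
    signal: pd.DataFrame

    def __post_init__(self):
        total = sum(f for _, _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise CloneError(f"component fractions sum to {total}, not 1")


def mixture_signal_from_segments(
    per_clone_segments: list[pd.DataFrame],
    clone_ids: list[str],
    fractions: list[float],
    purity: float,
) -> pd.DataFrame:
    """Expected relative coverage and BAF over the union segmentation.

    For a segment where clone k has parental copy counts (a_k, b_k) and the
    normal contributes (1, 1):

        r   = [sum_k f_k (a_k + b_k) + (1 - purity) * 2] / 2
        baf = [sum_k f_k b_k + (1 - purity) * 1] /
              [sum_k f_k (a_k + b_k) + (1 - purity) * 2]

    with baf undefined (NaN) where the denominator is zero.
    """
    if len(per_clone_segments) != len(fractions):
        raise CloneError("one fraction per clone required")
    if not (0.0 <= purity <= 1.0):
        raise CloneError("purity must be in [0, 1]")
    if abs(sum(fractions) - purity) > 1e-9:
        raise CloneError(
            f"tumor fractions sum to {sum(fractions)} but purity is {purity}"
        )
    chroms: list[str] = []
    for df in per_clone_segments:
        for c in df["chrom"]:
            if c not in chroms:
                chroms.append(c)
    rows = []
    for chrom in chroms:
        cuts = set()
        per_clone = []
        for df in per_clone_segments:
            sub = df[df["chrom"] == chrom]
            per_clone.append(sub)
            cuts.update(sub["start"].tolist())
            cuts.update(sub["end"].tolist())
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            num_b = (1.0 - purity) * 1.0
            denom = (1.0 - purity) * 2.0
            for f, sub in zip(fractions, per_clone):
                hit = sub[(sub["start"] <= s) & (sub["end"] >= e)]
                if len(hit) == 0:
                    a_k = b_k = 0  # region absent from this clone's genome
                else:
                    a_k = int(hit.iloc[0]["copies_A"])
                    b_k = int(hit.iloc[0]["copies_B"])
                num_b += f * b_k
                denom += f * (a_k + b_k)
            r = denom / 2.0
            baf = num_b / denom if denom > 0 else float("nan")
            rows.append((chrom, s, e, r, baf))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "expected_coverage_ratio", "expected_baf"]
    )


def expected_mixture_signal(
    clones: list[Clone],
    fractions: list[float],
    purity: float,
    segments: list[pd.DataFrame] | None = None,
    fasta_paths: list[str] | None = None,
) -> MixtureManifest:
    """Build the mixing manifest and per-segment expected signal for a sample
    of the given purity composed of ``clones`` at ``fractions`` (tumor
    fractions must sum to the purity; the normal takes the remainder)."""
    from .truth import derive_segments, segments_to_frame

    if len(clones) != len(fractions):
        raise CloneError("one fraction per clone required")
    if segments is None:
        segments = [segments_to_frame(derive_segments(c), c.clone_id) for c in clones]
    signal = mixture_signal_from_segments(
        segments, [c.clone_id for c in clones], list(fractions), purity
    )
    paths = fasta_paths or [None] * len(clones)
    components = [
        (c.clone_id, p, float(f)) for c, p, f in zip(clones, paths, fractions)
    ]
    components.append(("normal", None, float(1.0 - purity)))
    return MixtureManifest(components, purity, signal)


def write_mixture(manifest: MixtureManifest, out_dir) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(
            {
                "purity": manifest.purity,
                "components": [
                    {"id": cid, "fasta": path, "fraction": frac}
                    for cid, path, frac in manifest.components
                ],
            },
            fh,
            indent=2,
        )
    manifest.signal.round(6).to_csv(
        os.path.join(out_dir, "expected_signal.tsv"), sep="\t", index=False
    )
    log.info("wrote mixture manifest with %d components, %d signal segments",
             len(manifest.components), len(manifest.signal))
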