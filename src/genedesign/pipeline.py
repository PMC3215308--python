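"""Gene constructs and the configurable, constraint-screened optimization process.

A :class:`GeneConstruct` is an ordered list of typed components (coding
regions, fixed restriction sites, spacers, ...), each holding named
sequence properties; the construct's full sequence is the concatenation of
every component's 'Modified DNA'. Null-length components are allowed.

A :class:`StrategyConfig` lists optimization modules in execution order,
each of one of five kinds — Sequence optimization, mRNA structure
optimization, Gene manipulation, Constraint, Search strategy. Each cycle
clones a parent construct, applies the sequence-modifying modules to its
coding components, then evaluates every Constraint; candidates failing any
constraint are kept in the output but marked discarded, carrying the name
of the first failing constraint. Lineage (parent id per candidate) forms a
forest rooted at the input construct.
"""

from __future__ import annotations

import copy
import math
import random
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import metrics as _metrics
from .codon_usage import AdaptivenessTable, CodonLUT, build_lut
from .errors import StrategyError
from .folding import FoldEngine, default_engine
from .optimize import codon_optimize, mrna_optimize, silent_remove
from .search import find_repeats, search_queries
from .seqcore import (
    GeneticCode,
    NucSequence,
    STANDARD_CODE,
    parse_sequence,
    read_fasta,
    translate,
)

MODULE_KINDS = (
    "Sequence optimization",
    "mRNA structure optimization",
    "Gene manipulation",
    "Constraint",
    "Search strategy",
)

PROP_ORIGINAL_AA = "Original AA"
PROP_ORIGINAL_DNA = "Original DNA"
PROP_MODIFIED_DNA = "Modified DNA"


@dataclass(frozen=True)
class ComponentType:
    """A named schema of component properties; 'Modified DNA' is mandatory."""

    name: str
    properties: tuple[str, ...]

    def __post_init__(self) -> None:
        if PROP_MODIFIED_DNA not in self.properties:
            raise StrategyError(
                f"component type {self.name!r} must declare the {PROP_MODIFIED_DNA!r} property"
            )

    @property
    def is_coding(self) -> bool:
        return PROP_ORIGINAL_AA in self.properties


CODING = ComponentType(
    "Coding sequence", (PROP_ORIGINAL_AA, PROP_ORIGINAL_DNA, PROP_MODIFIED_DNA)
)
NON_CODING = ComponentType("Non-coding sequence", (PROP_ORIGINAL_DNA, PROP_MODIFIED_DNA))
RESTRICTION_SITE = ComponentType(
    "Restriction enzyme site", (PROP_ORIGINAL_DNA, PROP_MODIFIED_DNA)
)
MULTIPLE_CLONING_SITE = ComponentType(
    "Multiple cloning site", (PROP_ORIGINAL_DNA, PROP_MODIFIED_DNA)
)

BUILTIN_TYPES = {
    t.name: t for t in (CODING, NON_CODING, RESTRICTION_SITE, MULTIPLE_CLONING_SITE)
}


@dataclass
class Component:
    name: str
    ctype: ComponentType
    properties: dict[str, str] = field(default_factory=dict)

    @property
    def modified_dna(self) -> str:
        return self.properties.get(PROP_MODIFIED_DNA, "")

    @modified_dna.setter
    def modified_dna(self, value: str) -> None:
        self.properties[PROP_MODIFIED_DNA] = value


@dataclass
class GeneConstruct:
    """Ordered components; the full sequence concatenates their Modified DNA."""

    components: list[Component]
    name: str = "construct"

    def full_sequence(self) -> NucSequence:
        return NucSequence(
            "".join(c.modified_dna for c in self.components), name=self.name
        )

    def validate(self, code: GeneticCode = STANDARD_CODE) -> None:
        for c in self.components:
            dna = c.modified_dna
            if set(dna) - set("ACGT"):
                raise StrategyError(f"component {c.name!r}: invalid Modified DNA")
            aa = c.properties.get(PROP_ORIGINAL_AA)
            if c.ctype.is_coding and aa:
                got = translate(NucSequence(dna), code).residues
                if got != aa:
                    raise StrategyError(
                        f"component {c.name!r}: Modified DNA translates to {got!r}, "
                        f"expected {aa!r}"
                    )

    def clone(self) -> "GeneConstruct":
        return copy.deepcopy(self)

    @classmethod
    def from_file(cls, path) -> "GeneConstruct":
        """Load a construct definition (YAML mapping: name + component list)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneConstruct":
        comps = []
        for item in data.get("components", []):
            tname = item.get("type", "Coding sequence")
            if tname in BUILTIN_TYPES:
                ctype = BUILTIN_TYPES[tname]
            else:
                props = tuple(item.get("schema", (PROP_MODIFIED_DNA,)))
                ctype = ComponentType(tname, props)
            props_in = {
                k: parse_sequence(v).residues if k != PROP_ORIGINAL_AA else str(v).upper()
                for k, v in (item.get("properties") or {}).items()
            }
            if PROP_MODIFIED_DNA not in props_in and PROP_ORIGINAL_DNA in props_in:
                props_in[PROP_MODIFIED_DNA] = props_in[PROP_ORIGINAL_DNA]
            props_in.setdefault(PROP_MODIFIED_DNA, "")
            if (
                ctype.is_coding
                and PROP_ORIGINAL_AA not in props_in
                and props_in[PROP_MODIFIED_DNA]
            ):
                props_in[PROP_ORIGINAL_AA] = translate(
                    NucSequence(props_in[PROP_MODIFIED_DNA])
                ).residues
            comps.append(Component(item.get("name", f"component{len(comps) + 1}"), ctype, props_in))
        construct = cls(comps, name=data.get("name", "construct"))
        construct.validate()
        return construct


@dataclass
class StrategyModule:
    kind: str
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODULE_KINDS:
            raise StrategyError(
                f"unknown module kind {self.kind!r}; expected one of {MODULE_KINDS}"
            )


@dataclass
class StrategyConfig:
    """Ordered module list + cycle count + master seed."""

    modules: list[StrategyModule]
    cycles: int = 1
    seed: int = 0
    parent_policy: str = "original"  # or "best-so-far"
    parent_metric: str = "cai"

    def __post_init__(self) -> None:
        n_search = sum(1 for m in self.modules if m.kind == "Search strategy")
        if n_search > 1:
            raise StrategyError("at most one 'Search strategy' module is allowed")
        for m in self.modules:
            if m.kind == "Search strategy":
                self.parent_policy = m.params.get("policy", self.parent_policy)
                self.parent_metric = m.params.get("metric", self.parent_metric)
        if self.parent_policy not in ("original", "best-so-far"):
            raise StrategyError(f"unknown parent policy {self.parent_policy!r}")

    @classmethod
    def from_file(cls, path) -> "StrategyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "StrategyConfig":
        modules = [
            StrategyModule(
                kind=m["kind"], name=m["name"], params=dict(m.get("params") or {})
            )
            for m in data.get("modules", [])
        ]
        return cls(
            modules=modules,
            cycles=int(data.get("cycles", 1)),
            seed=int(data.get("seed", 0)),
        )


@dataclass
class CandidateRecord:
    """One optimization-cycle output with lineage and verdicts."""

    candidate_id: int
    parent_id: int  # 0 is the input construct
    construct: GeneConstruct
    sequence: str
    metric_values: dict[str, float] = field(default_factory=dict)
    verdicts: dict[str, bool] = field(default_factory=dict)
    passed: bool = True
    first_failed: str | None = None


# --- constraint evaluators ----------------------------------------------------

def constraint_exclude_queries(candidate: NucSequence, queries: str) -> bool:
    """Pass iff no query motif / enzyme site occurs in the full sequence."""
    hits = search_queries(candidate, queries)
    return all(h.count == 0 for h in hits)


def constraint_mrna_stability(
    candidate: NucSequence,
    engine: FoldEngine | None,
    threshold: float,
    window: int = 60,
    step: int = 10,
) -> bool:
    """Pass iff no moving-window folding energy falls below ``threshold``."""
    eng = engine or default_engine()
    track = _metrics.profile(candidate, lambda s: eng.energy(s), window=window, step=step)
    return track.min() >= threshold


def constraint_repeat_count(
    candidate: NucSequence, min_len: int = 8, max_count: float = 0
) -> bool:
    """Pass iff the number of repeat findings does not exceed ``max_count``."""
    findings = find_repeats(candidate, min_len=min_len)
    return len(findings) <= max_count


@dataclass
class PipelineResources:
    """Shared tables/engines handed to the optimization process."""

    adapt: AdaptivenessTable | None = None
    lut: CodonLUT | None = None
    engine: FoldEngine | None = None
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def require_lut(self) -> CodonLUT:
        if self.lut is None:
            if self.adapt is None:
                raise StrategyError("strategy requires a codon usage table / LUT")
            self.lut = build_lut(self.adapt, code=self.code)
        return self.lut


def _apply_module(
    module: StrategyModule,
    construct: GeneConstruct,
    res: PipelineResources,
    rng: random.Random,
) -> None:
    """Apply one sequence-modifying module in place, coding components only."""
    for comp in construct.components:
        if not comp.ctype.is_coding or not comp.modified_dna:
            continue
        seq = NucSequence(comp.modified_dna)
        sub_seed = rng.getrandbits(31)
        if module.name == "codon_optimize":
            out = codon_optimize(
                seq,
                res.require_lut(),
                seed=sub_seed,
                mode=module.params.get("mode", "all-positions"),
                per_position_probability=module.params.get("per_position_probability", 1.0),
                code=res.code,
            )
        elif module.name == "silent_remove":
            out = silent_remove(
                seq,
                targets=list(module.params.get("targets", [])),
                adapt_or_lut=res.require_lut(),
                seed=sub_seed,
                max_attempts=module.params.get("max_attempts", 100),
                code=res.code,
            )
        elif module.name == "mrna_optimize":
            out = mrna_optimize(
                seq,
                engine=res.engine,
                energy_min=module.params.get("energy_min", -math.inf),
                energy_max=module.params.get("energy_max", math.inf),
                lut=res.require_lut(),
                seed=sub_seed,
                max_iterations=module.params.get("max_iterations", 200),
                code=res.code,
            )
        else:
            raise StrategyError(f"unknown optimization module {module.name!r}")
        comp.modified_dna = out.sequence.residues


def _evaluate_constraint(
    module: StrategyModule, seq: NucSequence, res: PipelineResources
) -> bool:
    p = module.params
    if module.name == "check_cai":
        if res.adapt is None:
            raise StrategyError("check_cai requires an adaptiveness table")
        return _metrics.cai(seq, res.adapt, res.code) >= p.get("min", 0.8)
    if module.name == "check_gc":
        gc = _metrics.gc_content(seq)
        return p.get("min", 0.0) <= gc <= p.get("max", 100.0)
    if module.name == "exclude_queries":
        return constraint_exclude_queries(seq, p.get("queries", ""))
    if module.name == "mrna_stability":
        return constraint_mrna_stability(
            seq,
            res.engine,
            threshold=p.get("threshold", -10.0),
            window=p.get("window", 60),
            step=p.get("step", 10),
        )
    if module.name == "repeat_count":
        return constraint_repeat_count(
            seq, min_len=p.get("min_len", 8), max_count=p.get("max_count", 0)
        )
    raise StrategyError(f"unknown constraint module {module.name!r}")


def _candidate_metrics(seq: NucSequence, res: PipelineResources) -> dict[str, float]:
    values: dict[str, float] = {"gc": _metrics.gc_content(seq)}
    if res.adapt is not None and len(seq) % 3 == 0:
        try:
            values["cai"] = _metrics.cai(seq, res.adapt, res.code)
        except Exception:
            pass
    return values


def run_optimization(
    construct: GeneConstruct,
    strategy: StrategyConfig,
    resources: PipelineResources | None = None,
) -> list[CandidateRecord]:
    """Run the configured optimization process and return all candidates.

    Every cycle produces one candidate (kept even when discarded, for
    auditability). Deterministic for a fixed strategy seed.
    """
    res = resources or PipelineResources()
    construct.validate(res.code)
    rng = random.Random(strategy.seed)
    records: list[CandidateRecord] = []
    optimizer_kinds = (
        "Sequence optimization",
        "mRNA structure optimization",
        "Gene manipulation",
    )
    for cycle in range(1, strategy.cycles + 1):
        parent_id = 0
        parent = construct
        if strategy.parent_policy == "best-so-far":
            best = None
            for r in records:
                if r.passed and strategy.parent_metric in r.metric_values:
                    if best is None or (
                        r.metric_values[strategy.parent_metric]
                        > best.metric_values[strategy.parent_metric]
                    ):
                        best = r
            if best is not None:
                parent, parent_id = best.construct, best.candidate_id
        candidate = parent.clone()
        cycle_rng = random.Random(rng.getrandbits(31))
        try:
            for module in strategy.modules:
                if module.kind in optimizer_kinds:
                    _apply_module(module, candidate, res, cycle_rng)
        except StrategyError:
            raise
        except Exception as exc:
            raise StrategyError(f"cycle {cycle}: module failure: {exc}") from exc
        full = candidate.full_sequence()
        verdicts: dict[str, bool] = {}
        first_failed = None
        for module in strategy.modules:
            if module.kind != "Constraint":
                continue
            ok = _evaluate_constraint(module, full, res)
            verdicts[module.name] = ok
            if not ok and first_failed is None:
                first_failed = module.name
        records.append(
            CandidateRecord(
                candidate_id=cycle,
                parent_id=parent_id,
                construct=candidate,
                sequence=full.residues,
                metric_values=_candidate_metrics(full, res),
                verdicts=verdicts,
                passed=first_failed is None,
                first_failed=first_failed,
            )
        )
    return records


def candidates_to_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "candidate_id": r.candidate_id,
            "parent_id": r.parent_id,
            "passed": r.passed,
            "first_failed": r.first_failed or "",
            "sequence": r.sequence,
        }
        row.update({f"metric_{k}": v for k, v in r.metric_values.items()})
        row.update({f"constraint_{k}": v for k, v in r.verdicts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# --- batch analysis -----------------------------------------------------------

_BATCH_METRICS = ("cai", "nc", "gc", "energy", "length")


def _analyze_one(args) -> dict:
    name, residues, wanted, w_map, engine_kind = args
    seq = NucSequence(residues, name=name)
    row: dict = {"name": name, "length": len(seq)}
    from .folding import BuiltinFoldEngine

    for m in wanted:
        try:
            if m == "gc":
                row["gc"] = _metrics.gc_content(seq)
            elif m == "nc":
                row["nc"] = _metrics.nc(seq)
            elif m == "cai":
                if w_map is None:
                    raise StrategyError("CAI requested without a reference table")
                adapt = AdaptivenessTable(rscu={}, rscu_max={}, w=w_map)
                row["cai"] = _metrics.cai(seq, adapt)
            elif m == "energy":
                row["energy"] = BuiltinFoldEngine().energy(seq)
        except Exception as exc:
            row.setdefault("error", str(exc))
    return row


def batch_analyze(
    source,
    metric_set: tuple[str, ...] = ("cai", "nc", "gc"),
    adapt: AdaptivenessTable | None = None,
    processes: int = 1,
) -> pd.DataFrame:
    """One metrics row per FASTA record (or NucSequence list), order preserved.

    Per-record failures land in an 'error' column; the batch continues.
    With ``processes > 1`` records are scored in a local process pool,
    which preserves input order.
    """
    unknown = set(metric_set) - set(_BATCH_METRICS)
    if unknown:
        raise StrategyError(f"unknown batch metrics: {sorted(unknown)}")
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        seqs = read_fasta(source)
    else:
        seqs = list(source)
    w_map = dict(adapt.w) if adapt is not None else None
    jobs = [(s.name, s.residues, tuple(metric_set), w_map, "builtin") for s in seqs]
    if processes > 1 and jobs:
        with ProcessPoolExecutor(max_workers=processes) as pool:
            rows = list(pool.map(_analyze_one, jobs))
    else:
        rows = [_analyze_one(j) for j in jobs]
    columns = ["name", "length"] + [m for m in metric_set if m != "length"]
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=columns)
    return frame
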