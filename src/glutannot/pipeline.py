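"""Pipeline orchestration: annotate, compare, promoter scan, phylogeny.

Each run function composes the library stages over a FASTA input and writes
a report whose header records the package version, a hash of the effective
configuration, and the seed, so identical configs give identical bytes.
Per-record problems (missing anchor, premature stops, unknown types) are
logged as warnings and the run continues; hard errors are reserved for
malformed inputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .anatomy import (
    DomainPartition,
    classify_subunit_type,
    cysteine_census,
    domain_sequences,
    partition_domains,
    strip_signal_peptide,
)
from .insertions import AlignParams, detect_insertions
from .phylo import bootstrap_support, median_joining_network, neighbor_joining, newick, p_distance_matrix
from .promoter import DEFAULT_ELEMENTS, load_elements, scan_elements
from .repeats import DEFAULT_LEXICON, load_lexicon, motif_census, segment_repeats
from .seq_io import GeneRecord, pair_promoters, read_fasta, translate_orf, write_report

log = logging.getLogger("glutannot")


@dataclass
class RunConfig:
    lexicon_path: str | None = None
    elements_path: str | None = None
    align_params: AlignParams = field(default_factory=AlignParams)
    min_block: int = 30
    min_consecutive_motifs: int = 3
    bootstrap_reps: int = 1000
    distance_model: str = "p"
    mj_epsilon: int = 0
    mj_weights: float = 10.0
    seed: int = 0

    @property
    def lexicon(self):
        return load_lexicon(self.lexicon_path) if self.lexicon_path else DEFAULT_LEXICON

    @property
    def elements(self):
        return tuple(load_elements(self.elements_path)) if self.elements_path else DEFAULT_ELEMENTS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "align_params" in data:
            data["align_params"] = AlignParams(**data["align_params"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {
            "version": __version__,
            "config": self.config_hash(),
            "seed": self.seed,
        }


def annotate_record(rec: GeneRecord, config: RunConfig) -> dict:
    """Full structural annotation of one gene (one Table-2-shaped row)."""
    tr = translate_orf(rec.orf_dna, id=rec.id)
    if tr.status != "ok":
        log.warning(tr.message)
    mature = strip_signal_peptide(tr.protein)
    if mature.status != "ok":
        log.warning(mature.message)
    part = partition_domains(mature, config.lexicon, config.min_consecutive_motifs)
    if part.status != "ok":
        log.warning(part.message)
    if mature.subunit_type == "unknown":
        mature.subunit_type = classify_subunit_type(
            mature, DomainPartition.span_length(part.n_terminal)
        )
    cys = cysteine_census(mature, part)
    rep = domain_sequences(mature, part)["repetitive"]
    census = motif_census(segment_repeats(rep, config.lexicon)) if rep else None
    row = {
        "id": rec.id,
        "subunit_type": mature.subunit_type,
        "orf_bp": len(rec.orf_dna),
        "n_codons": tr.n_codons,
        "trailing_stops": tr.n_trailing_stops,
        "signal_len": len(mature.signal_peptide),
        "nterm_len": DomainPartition.span_length(part.n_terminal),
        "rep_len": DomainPartition.span_length(part.repetitive),
        "cterm_len": DomainPartition.span_length(part.c_terminal),
        "mature_len": len(mature.residues),
        "n_tri": census.n_tri if census else 0,
        "n_hexa": census.n_hexa if census else 0,
        "n_nona": census.n_nona if census else 0,
        "rep_unassigned": census.n_unassigned_residues if census else 0,
        "cys_nterm": cys.n_cys_nterm,
        "cys_rep": cys.n_cys_rep,
        "cys_cterm": cys.n_cys_cterm,
        "cys_total": cys.n_cys_total,
        "cys_conforms": cys.conforms,
        "status": "ok" if tr.status == "ok" and mature.status == "ok" else "warning",
    }
    return row


def run_annotate(fasta: str | Path, config: RunConfig, out: str | Path, format: str = "tsv") -> list[dict]:
    from .seq_io import FastaError

    try:
        records = pair_promoters(read_fasta(fasta, kind="dna"))
    except FastaError as exc:
        # empty input is a soft condition: emit a header-only report
        if "empty" not in str(exc):
            raise
        records = []
        log.warning("no records read from %s", fasta)
    rows = [annotate_record(r, config) for r in records]
    write_report(rows, out, format=format, meta=config.meta())
    return rows


def run_compare(
    query_fasta: str | Path, ref_fasta: str | Path, config: RunConfig,
    out: str | Path, format: str = "tsv",
) -> list[dict]:
    """Detect insertion blocks in each query against the same-type reference."""
    queries = read_fasta(query_fasta, kind="dna")
    refs = read_fasta(ref_fasta, kind="dna")
    ref_by_type: dict[str, object] = {}
    for r in refs:
        m = strip_signal_peptide(translate_orf(r.orf_dna, id=r.id).protein)
        if m.subunit_type in ref_by_type:
            raise ValueError(f"multiple references of type {m.subunit_type!r}")
        ref_by_type[m.subunit_type] = m
    rows = []
    for q in queries:
        mq = strip_signal_peptide(translate_orf(q.orf_dna, id=q.id).protein)
        ref = ref_by_type.get(mq.subunit_type)
        if ref is None:
            log.warning("%s: no %s-type reference; skipped", q.id, mq.subunit_type)
            continue
        blocks = detect_insertions(
            mq, ref, min_block=config.min_block,
            params=config.align_params, lexicon=config.lexicon,
        )
        for b in blocks:
            ev = b.duplication_evidence
            rows.append({
                "query_id": q.id,
                "ref_id": ref.id,
                "start": b.query_span[0],
                "end": b.query_span[1],
                "length": b.length,
                "n_tri": b.motif_census.n_tri,
                "n_hexa": b.motif_census.n_hexa,
                "n_nona": b.motif_census.n_nona,
                "unassigned": b.motif_census.n_unassigned_residues,
                "flank": ev.flank if ev else "",
                "identity_pct": f"{ev.identity_pct:.1f}" if ev else "",
                "n_variants": len(ev.variant_positions) if ev else "",
            })
    write_report(rows, out, format=format, meta=config.meta())
    return rows


def run_promoter(fasta: str | Path, config: RunConfig, out: str | Path, format: str = "tsv") -> list[dict]:
    records = read_fasta(fasta, kind="dna")
    rows = []
    for rec in records:
        ann = scan_elements(rec.orf_dna, config.elements, promoter_id=rec.id)
        row: dict = {"id": rec.id}
        for hit in ann.hits:
            row[f"{hit.name}_status"] = hit.status
            row[f"{hit.name}_offset"] = hit.offset if hit.offset else ""
            row[f"{hit.name}_observed"] = hit.observed
            row[f"{hit.name}_nsubs"] = len(hit.substitutions)
        rows.append(row)
    write_report(rows, out, format=format, meta=config.meta())
    return rows


def run_phylo(aligned_fasta: str | Path, config: RunConfig, out_dir: str | Path) -> dict:
    """NJ tree (newick, bootstrap supports as internal labels) + MJ network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(aligned_fasta, kind="dna")
    aligned = [(r.id, r.orf_dna) for r in records]
    meta = config.meta()
    header = "".join(f"# {k}: {meta[k]}\n" for k in sorted(meta))

    tree_path = out_dir / "tree.nwk"
    if len(aligned) >= 3:
        tree = bootstrap_support(
            aligned, n_reps=config.bootstrap_reps, seed=config.seed,
            model=config.distance_model,
        )
        tree_path.write_text(header + newick(tree, include_support=True) + "\n")
    else:
        log.warning("fewer than 3 sequences; NJ tree skipped")
        tree = None
        tree_path.write_text(header + "# NJ skipped: fewer than 3 sequences\n")

    net = median_joining_network(
        aligned, epsilon=config.mj_epsilon, weights=config.mj_weights
    )
    node_names = {}
    obs_counter = 0
    med_counter = 0
    for n in sorted(net.graph.nodes):
        info = net.node_info[n]
        if info["type"] == "observed":
            node_names[n] = "|".join(sorted(info["members"]))
        else:
            med_counter += 1
            node_names[n] = f"median_{med_counter}"
    with open(out_dir / "network_nodes.tsv", "w") as fh:
        fh.write(header)
        fh.write(f"# epsilon: {net.params['epsilon']}\n# weights: {net.params['weights']}\n")
        fh.write("node\ttype\tmembers\n")
        for n in sorted(net.graph.nodes):
            info = net.node_info[n]
            fh.write(f"{node_names[n]}\t{info['type']}\t{','.join(sorted(info['members']))}\n")
    with open(out_dir / "network_edges.tsv", "w") as fh:
        fh.write(header)
        fh.write("node1\tnode2\tmutations\n")
        for u, v, data in sorted(net.graph.edges(data=True), key=lambda e: (node_names[e[0]], node_names[e[1]])):
            a, b = sorted((node_names[u], node_names[v]))
            fh.write(f"{a}\t{b}\t{data['mutations']}\n")
    return {"tree": tree, "network": net, "out_dir": out_dir}
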