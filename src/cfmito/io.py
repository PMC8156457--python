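"""Standard-format I/O: SAM (via pysam), VCF v4.2 text, fragment/manifest TSV.

Internal coordinates are 1-based; deletions are represented at the first
deleted base and insertions anchored to the preceding base, so the VCF layer
converts to/from the anchored REF/ALT convention.  Fragments wrapping the
circular origin are split into two SAM records (the second supplementary) but
round-trip losslessly through the native fragment TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .reference import MtReference
from .simulate import AlignedFragment, TruthSample
from .variants import DEL, INS, SNV, MtVariant, VariantKey

CONTIG = "chrM"

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##FILTER=<ID=LOW_DEPTH,Description="Site depth below threshold">
##FILTER=<ID=HOMOPOLYMER,Description="Variant within a homopolymer run">
##FILTER=<ID=LOW_ALT_SUPPORT,Description="Alternative allele support below threshold">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at site">
##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternative allele read count">
##INFO=<ID=RD,Number=1,Type=Integer,Description="Reference allele read count">
##INFO=<ID=HPCLASS,Number=1,Type=String,Description="Heteroplasmy class">
##INFO=<ID=HPFRAC,Number=1,Type=Float,Description="Heteroplasmy fraction">
##INFO=<ID=HRUN,Number=1,Type=Integer,Description="Homopolymer run length at site">
{extra}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _vcf_alleles(key: VariantKey, ref: MtReference) -> tuple[int, str, str]:
    """Convert internal variant representation to anchored VCF POS/REF/ALT."""
    if key.vtype == SNV:
        return key.pos, key.ref, key.alt
    if key.vtype == DEL:
        if key.pos > 1:
            anchor = ref.base(key.pos - 1)
            return key.pos - 1, anchor + key.ref, anchor
        nxt = ref.base(key.pos + len(key.ref))
        return key.pos, key.ref + nxt, nxt
    if key.vtype == INS:
        anchor = ref.base(key.pos)
        return key.pos, anchor, anchor + key.alt
    raise ValueError(f"unknown variant type {key.vtype!r}")


def _key_from_vcf(pos: int, vref: str, valt: str) -> VariantKey:
    if len(vref) == 1 and len(valt) == 1:
        return VariantKey(pos, vref, valt, SNV)
    if len(vref) > len(valt):  # deletion
        if vref.startswith(valt):  # left anchor
            return VariantKey(pos + len(valt), vref[len(valt):], "", DEL)
        if vref.endswith(valt):  # right anchor (origin-adjacent)
            return VariantKey(pos, vref[: len(vref) - len(valt)], "", DEL)
    if len(valt) > len(vref) and valt.startswith(vref):  # insertion
        return VariantKey(pos + len(vref) - 1, "", valt[len(vref):], INS)
    raise ValueError(f"cannot normalise VCF alleles {vref}>{valt} at {pos}")


def write_vcf(
    variants: Sequence[MtVariant],
    ref: MtReference,
    path: str | Path,
    extra_headers: Sequence[str] = (),
) -> None:
    """Write called variants as VCF v4.2 (PASS or semicolon-joined filter flags)."""
    extra = "".join(h.rstrip("\n") + "\n" for h in extra_headers)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=CONTIG, length=ref.length, extra=extra))
        for v in sorted(variants, key=lambda v: (v.pos, v.key.alt)):
            pos, vref, valt = _vcf_alleles(v.key, ref)
            filt = ";".join(sorted(v.filter_flags)) or "PASS"
            info = f"DP={v.depth};AD={v.alt_reads};RD={v.ref_reads}"
            if v.heteroplasmy_fraction is not None:
                info += f";HPCLASS={v.heteroplasmy_class};HPFRAC={v.heteroplasmy_fraction:.6g}"
            if v.homopolymer_run_length:
                info += f";HRUN={v.homopolymer_run_length}"
            fh.write(f"{CONTIG}\t{pos}\t.\t{vref}\t{valt}\t.\t{filt}\t{info}\n")


def read_vcf(path: str | Path) -> list[MtVariant]:
    """Read a VCF emitted by :func:`write_vcf` back into variant records."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, vref, valt, _, filt, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            v = MtVariant(
                key=_key_from_vcf(int(pos), vref, valt),
                depth=int(fields.get("DP", 0)),
                alt_reads=int(fields.get("AD", 0)),
                ref_reads=int(fields.get("RD", 0)),
                homopolymer_run_length=int(fields.get("HRUN", 0)),
                filter_flags=set() if filt in ("PASS", ".") else set(filt.split(";")),
            )
            if "HPCLASS" in fields:
                v.heteroplasmy_class = fields["HPCLASS"]
                v.heteroplasmy_fraction = float(fields["HPFRAC"])
            out.append(v)
    return out


def write_truth_vcf(truth: TruthSample, ref: MtReference, path: str | Path) -> None:
    """Simulator ground truth as VCF with origin-tissue and heteroplasmy INFO keys."""
    extra = [
        '##INFO=<ID=ORIGIN,Number=.,Type=String,Description="Truth tissue origin">',
        '##INFO=<ID=HP,Number=1,Type=Float,Description="Truth heteroplasmy">',
        f"##truth_sample={truth.sample_id}",
    ]
    origins = {}
    for key in truth.maternal_variants:
        origins.setdefault(key, []).append("maternal")
    for key in truth.foetal_variants - truth.maternal_variants:
        origins.setdefault(key, []).append("foetal")
    for key in truth.leukocyte_private:
        origins.setdefault(key, []).append("leukocyte")
    for key in truth.cf_private:
        origins.setdefault(key, []).append("cf")
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contig=CONTIG, length=ref.length,
                                    extra="".join(h + "\n" for h in extra)))
        for key in sorted(origins):
            pos, vref, valt = _vcf_alleles(key, ref)
            info = f"ORIGIN={','.join(origins[key])};HP={truth.heteroplasmy[key]:.6g}"
            fh.write(f"{CONTIG}\t{pos}\t.\t{vref}\t{valt}\t.\tPASS\t{info}\n")


# ------------------------------------------------------------------ fragments


def write_fragments_tsv(fragments: Iterable[AlignedFragment], path: str | Path) -> None:
    """Native lossless fragment table (alleles as comma-joined HGVS-like tokens)."""
    from .variants import hgvs_name

    with open(path, "w") as fh:
        fh.write("sample_id\tstart\tlength\torigin\talleles\n")
        for f in fragments:
            tokens = ",".join(hgvs_name(a) for a in f.alleles)
            fh.write(f"{f.sample_id}\t{f.start}\t{f.length}\t{f.origin}\t{tokens}\n")


def read_fragments_tsv(path: str | Path) -> list[AlignedFragment]:
    from .variants import parse_hgvs

    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            sid, start, length, origin, tokens = (line.rstrip("\n").split("\t") + [""])[:5]
            alleles = tuple(parse_hgvs(t) for t in tokens.split(",") if t)
            out.append(AlignedFragment(sid, int(start), int(length), alleles, origin))
    return out


# ------------------------------------------------------------------ SAM


def _fragment_to_segments(frag: AlignedFragment, ref: MtReference):
    """(pos0, cigar, seq) alignment segments; wrapped fragments yield two."""
    L = ref.length
    start0 = (frag.start - 1) % L
    spans = [(start0, min(start0 + frag.length, L))]
    if start0 + frag.length > L:
        spans.append((0, start0 + frag.length - L))
    events = {a.pos: a for a in frag.alleles}
    segments = []
    for s0, e0 in spans:
        seq_parts, cigar, op_run = [], [], [None, 0]

        def emit(op: str, n: int = 1):
            if op_run[0] == op:
                op_run[1] += n
            else:
                if op_run[0] is not None:
                    cigar.append(f"{op_run[1]}{op_run[0]}")
                op_run[0], op_run[1] = op, n

        for pos in range(s0 + 1, e0 + 1):  # 1-based positions
            ev = events.get(pos)
            if ev is None or ev.vtype == INS:
                seq_parts.append(ref.base(pos))
                emit("M")
                if ev is not None:  # insertion after anchor base
                    seq_parts.append(ev.alt)
                    emit("I", len(ev.alt))
            elif ev.vtype == SNV:
                seq_parts.append(ev.alt)
                emit("M")
            elif ev.vtype == DEL:
                emit("D", len(ev.ref))
        emit("END", 0)
        segments.append((s0, "".join(c for c in cigar), "".join(seq_parts)))
    return segments


def write_sam(
    fragments: Sequence[AlignedFragment], ref: MtReference, path: str | Path
) -> None:
    """Minimal SAM via pysam; origin tissue kept in the ``XO`` tag."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": CONTIG, "LN": ref.length}]}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, frag in enumerate(fragments):
            segments = _fragment_to_segments(frag, ref)
            for j, (pos0, cigar, seq) in enumerate(segments):
                a = pysam.AlignedSegment(header)
                a.query_name = f"{frag.sample_id}.f{i}"
                a.flag = 0 if j == 0 else 2048
                a.reference_id = 0
                a.reference_start = pos0
                a.mapping_quality = 60
                a.cigarstring = cigar
                a.query_sequence = seq
                a.set_tag("XO", frag.origin)
                out.write(a)


def read_sam(path: str | Path, sample_id: str = "") -> list[AlignedFragment]:
    """Read aligned records back into fragments, recovering variant payloads.

    Each SAM record becomes one fragment (origin-wrapped fragments therefore
    come back as two part-fragments, which pile up identically).
    """
    out = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        ref_len = fh.header.get_reference_length(CONTIG)
        refseq = None
        for rec in fh:
            if rec.is_unmapped:
                continue
            alleles = []
            qpos, rpos = 0, rec.reference_start  # rpos 0-based
            seq = rec.query_sequence or ""
            for op, n in rec.cigartuples or []:
                if op == 0:  # M
                    for k in range(n):
                        alleles.append(("M", rpos + k + 1, seq[qpos + k]))
                    qpos += n
                    rpos += n
                elif op == 1:  # I anchored to previous ref base
                    alleles.append(("I", rpos, seq[qpos : qpos + n]))
                    qpos += n
                elif op == 2:  # D at first deleted base
                    alleles.append(("D", rpos + 1, n))
                    rpos += n
            out.append(
                (rec.query_name, rec.reference_start + 1,
                 rec.reference_end - rec.reference_start,
                 rec.get_tag("XO") if rec.has_tag("XO") else "", alleles)
            )
    return out


def sam_to_fragments(path: str | Path, ref: MtReference) -> list[AlignedFragment]:
    """Fragments with variant payloads from a SAM file, by comparison to ``ref``."""
    fragments = []
    for name, start, length, origin, ops in read_sam(path):
        alleles = []
        for kind, pos, payload in ops:
            if kind == "M":
                if payload != ref.base(pos):
                    alleles.append(VariantKey(pos, ref.base(pos), payload, SNV))
            elif kind == "I":
                alleles.append(VariantKey(pos, "", payload, INS))
            elif kind == "D":
                deleted = "".join(ref.base(pos + k) for k in range(payload))
                alleles.append(VariantKey(pos, deleted, "", DEL))
        sid = name.rsplit(".f", 1)[0]
        fragments.append(
            AlignedFragment(sid, start, length, tuple(sorted(set(alleles))), origin)
        )
    return fragments


# ------------------------------------------------------------------ manifests


def write_manifest(truths: Sequence[TruthSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "region": [t.region_label for t in truths],
            "tube_type": [t.tube_type for t in truths],
            "transport_days": [t.transport_days for t in truths],
            "foetal_fraction": [t.foetal_fraction for t in truths],
            "total_reads": [t.total_reads for t in truths],
        }
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")
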