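"""Independent brute-force oracles, deliberately naive and object-level.

These reimplement each operation from first principles (full-sequence
translation, exhaustive predicate evaluation, plain tallies and sorts) so
the package's vectorized paths can be checked against them on small random
instances.
"""

from __future__ import annotations

from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def classify_oracle(key, tx, model):
    """Consequence by mutating the chromosome and translating both CDSs."""
    pos = key.pos
    in_exon = any(s <= pos <= e for s, e in tx.exons)
    first_start, last_end = tx.exons[0][0], tx.exons[-1][1]
    if not in_exon:
        if not first_start <= pos <= last_end:
            return "intergenic"
        for s, e in tx.exons:
            if (s != first_start and s - 2 <= pos <= s - 1) or (
                e != last_end and e + 1 <= pos <= e + 2
            ):
                return "essential_splice"
        return "intronic"
    analyzable = bool(tx.cds) and sum(e - s + 1 for s, e in tx.cds) % 3 == 0
    in_cds = any(s <= pos <= e for s, e in tx.cds)
    if not (analyzable and in_cds):
        return "utr"
    chrom_seq = model.seq(tx.chrom, 1, len(model._seq[tx.chrom]))
    assert chrom_seq[pos - 1] == key.ref
    mutant = chrom_seq[: pos - 1] + key.alt + chrom_seq[pos:]

    def protein(genome):
        cds = "".join(genome[s - 1: e] for s, e in tx.cds)
        if tx.strand == "-":
            cds = cds.translate(_COMP)[::-1]
        return str(Seq(cds).translate())

    ref_p, alt_p = protein(chrom_seq), protein(mutant)
    ref_stops = {i for i, a in enumerate(ref_p) if a == "*"}
    alt_stops = {i for i, a in enumerate(alt_p) if a == "*"}
    if ref_stops != alt_stops:
        return "nonsense"
    if ref_p != alt_p:
        return "nonsynonymous"
    return "synonymous"


def filter_oracle(cohort, cfg):
    """Surviving observations by exhaustive per-observation evaluation."""
    anns = list(cohort.annotations())
    ann_by_key = {}
    for a in anns:
        ann_by_key.setdefault(a.key, []).append(a)
    carriers = {}
    for o in cohort.observations():
        carriers.setdefault(o.key, set()).add(o.sample_id)
    excluded_keys = set()
    for o in cohort.observations():
        if o.sample_id in set(cfg.exclude_in_samples):
            excluded_keys.add(o.key)
    if not cfg.allele_exact_controls:
        positions = {(k.chrom, k.pos) for k in excluded_keys}
        excluded_keys = {
            k for k in carriers if (k.chrom, k.pos) in positions
        }

    surviving = set()
    for o in cohort.observations():
        ok = True
        if cfg.min_coverage is not None and o.coverage < cfg.min_coverage:
            ok = False
        if cfg.max_coverage is not None and o.coverage > cfg.max_coverage:
            ok = False
        if cfg.min_vaf is not None and o.vaf < cfg.min_vaf:
            ok = False
        if cfg.max_vaf is not None and o.vaf > cfg.max_vaf:
            ok = False
        if cfg.zygosity is not None and o.zygosity != cfg.zygosity:
            ok = False
        if cfg.consequences is not None:
            if not any(a.consequence in cfg.consequences
                       for a in ann_by_key.get(o.key, [])):
                ok = False
        for name in cfg.exclude_in_sets:
            if cohort.site_sets[name].contains(o.key):
                ok = False
        if cfg.min_phylop is not None:
            clade, thr = cfg.min_phylop
            scores = [
                a.phylop.get(clade)
                for a in ann_by_key.get(o.key, [])
                if a.phylop.get(clade) is not None
                and a.phylop.get(clade) == a.phylop.get(clade)  # not NaN
            ]
            if scores:
                if max(scores) < thr:
                    ok = False
            elif not cfg.missing_scores_pass:
                ok = False
        if cfg.panel_include is not None:
            if not any(a.gene_id in cfg.panel_include
                       for a in ann_by_key.get(o.key, [])):
                ok = False
        if cfg.panel_exclude is not None:
            if any(a.gene_id in cfg.panel_exclude
                   for a in ann_by_key.get(o.key, [])):
                ok = False
        if o.key in excluded_keys:
            ok = False
        if cfg.max_carrier_samples is not None and \
                len(carriers[o.key]) > cfg.max_carrier_samples:
            ok = False
        if ok:
            surviving.add((o.key, o.sample_id))
    return surviving


def hits_oracle(cohort, model, unit_level="gene"):
    """(unit, sample) hits by plain per-pair counting over annotations."""
    units = {}
    for a in cohort.annotations():
        if unit_level == "gene":
            if a.consequence == "intergenic" or not a.gene_id:
                continue
            unit = a.gene_id
        else:
            if a.exon_index is None:
                continue
            unit = f"{a.gene_id}|{a.transcript_id}|exon{a.exon_index}"
        units.setdefault(a.key, set()).add(unit)
    per_pair = {}
    for o in cohort.observations():
        for unit in units.get(o.key, ()):
            per_pair.setdefault((unit, o.sample_id), set()).add(o.key)
    threshold = 1 if model == "dominant" else 2
    return {
        pair: keys for pair, keys in per_pair.items() if len(keys) >= threshold
    }


def summarize_oracle(hit_pairs):
    """Unit summaries recomputed from a {(unit, sample): keys} mapping."""
    out = {}
    units = {u for u, _ in hit_pairs}
    for unit in units:
        samples = {s for (u, s) in hit_pairs if u == unit}
        key_carriers = {}
        for (u, s), keys in hit_pairs.items():
            if u != unit:
                continue
            for k in keys:
                key_carriers.setdefault(k, set()).add(s)
        out[unit] = {
            "n_samples": len(samples),
            "n_total_variants": len(key_carriers),
            "n_unique_variants": sum(
                1 for c in key_carriers.values() if len(c) == 1
            ),
            "max_sample_burden": max(
                len(keys) for (u, s), keys in hit_pairs.items() if u == unit
            ),
        }
    return out


def sort_oracle(rows, keys):
    """Comparison sort with the documented comparator (missing -> bottom)."""
    import math

    def sort_key(row):
        parts = []
        for fieldname, direction in keys:
            v = row[fieldname]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                parts.append(math.inf)
            else:
                parts.append(-v if direction == "desc" else v)
        parts.append(row["unit_id"])
        return tuple(parts)

    return [r["unit_id"] for r in sorted(rows, key=sort_key)]
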