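"""Independent naive re-implementation of the query semantics.

Deliberately written as plain single-pass loops over in-memory records,
sharing no code with the engine: it re-derives MAF, missing ratio, major
genotype, masking and the pattern/discrimination rules from their
definitions.  Property tests compare the chunked concurrent engine against
this oracle.
"""

from collections import Counter


def _norm(call):
    return tuple(sorted(call.allele_indices))


def _masked_group_calls(run, gf):
    """ind -> normalized call, after numeric-threshold masking."""
    out = {}
    for ind in gf.individuals:
        call = run.calls.get(ind)
        if call is None:
            continue
        vals = run.numeric_values.get(ind, {})
        keep = True
        for fname, minimum in gf.numeric_thresholds.items():
            if fname not in vals or vals[fname] < minimum:
                keep = False
        if keep:
            out[ind] = _norm(call)
    return out


def _group_decision(run, gf):
    """(passes, major_genotype) for one group at one variant."""
    calls = _masked_group_calls(run, gf)
    n_sel = len(gf.individuals)
    n_called = len(calls)
    missing_ratio = (n_sel - n_called) / n_sel

    geno = Counter(calls.values())
    major = None
    major_ratio = 0.0
    if n_called:
        best = max(geno.values())
        major = sorted(g for g, c in geno.items() if c == best)[0]
        major_ratio = best / n_called

    alleles = Counter(a for g in calls.values() for a in g)
    if alleles:
        by_freq = sorted(alleles.values(), reverse=True)
        maf = by_freq[1] / sum(by_freq) if len(by_freq) >= 2 else 0.0
    else:
        maf = None

    ok = True
    if gf.max_missing_ratio is not None and missing_ratio > gf.max_missing_ratio:
        ok = False
    if gf.maf_min is not None or gf.maf_max is not None:
        lo = gf.maf_min if gf.maf_min is not None else 0.0
        hi = gf.maf_max if gf.maf_max is not None else 0.5
        if maf is None or maf < lo or maf > hi:
            ok = False
    if gf.pattern == "ALL_OR_MOSTLY_SAME":
        if n_called == 0 or major_ratio < gf.similarity_ratio:
            ok = False
    return ok, major


def _variant_ok(rec, run, vf):
    if vf.variant_types is not None and rec.variant_type not in vf.variant_types:
        return False
    if vf.allele_count_min is not None and len(rec.known_alleles) < vf.allele_count_min:
        return False
    if vf.allele_count_max is not None and len(rec.known_alleles) > vf.allele_count_max:
        return False
    if vf.sequences is not None and rec.sequence not in vf.sequences:
        return False
    if vf.position_min is not None and rec.position < vf.position_min:
        return False
    if vf.position_max is not None and rec.position > vf.position_max:
        return False
    if vf.effects:
        if not any(a.effect in vf.effects for a in run.annotations):
            return False
    if vf.gene_names:
        if not any(a.gene_name in vf.gene_names for a in run.annotations):
            return False
    return True


def naive_find(records, query):
    """Matching variant ids, by sequential full scan of (record, run) pairs."""
    out = []
    for rec, run in records:
        if not _variant_ok(rec, run, query.variant_filter):
            continue
        decisions = [
            _group_decision(run, gf) for gf in (query.group1, query.group2) if gf is not None
        ]
        if query.discriminate:
            (p1, m1), (p2, m2) = decisions
            if not (p1 and p2 and m1 is not None and m2 is not None and m1 != m2):
                continue
        elif not all(p for p, _ in decisions):
            continue
        out.append(rec.variant_id)
    return out
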