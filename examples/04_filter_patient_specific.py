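"""Reduce SV predictions to patient-specific candidates.

Three filters in sequence: read-pair support (>= 5 independent pairs),
overlap with a catalogue of known common SVs (>= 80 % removes the
prediction), and family comparison (events shared with unaffected relatives
are not candidates for the discordant phenotype).
"""

import abtmap as m

mk = lambda name, n, a, b: m.SVPrediction(
    "deletion",
    m.GenomicInterval("chr3", a, a + 100),
    m.GenomicInterval("chr3", b, b + 100),
    tuple(f"{name}_{i}" for i in range(n)),
    ("-", "+"),
    name=name,
)

affected = [mk("weak", 3, 10_000, 20_000), mk("known", 9, 50_000, 80_000),
            mk("shared", 8, 120_000, 150_000), mk("private", 7, 200_000, 240_000)]
sibling = [mk("sib_shared", 11, 120_100, 150_200)]
catalogue = [m.FeatureRecord(m.GenomicInterval("chr3", 49_000, 81_000), "known_sv", "dgv_1",
                             {"sv_type": "deletion"})]

survivors, rep = m.filter_by_support(affected, 5)
print(f"support filter: {rep.input_count} -> {rep.survivors}  "
      f"(dropped: {[n for n, r in rep.dispositions if r != 'retained']})")
survivors, rep = m.filter_known(survivors, catalogue, 0.8)
print(f"known-SV filter: {rep.input_count} -> {rep.survivors}  "
      f"(dropped: {[n for n, r in rep.dispositions if r != 'retained']})")
survivors, rep = m.patient_specific({"affected": survivors, "sibling": sibling}, "affected")
print(f"family filter: {rep.input_count} -> {rep.survivors}  "
      f"(dropped: {[n for n, r in rep.dispositions if r != 'retained']})")
print(f"patient-specific candidates: {[p.name for p in survivors]}")
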