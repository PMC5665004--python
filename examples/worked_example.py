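"""End-to-end walkthrough: synthetic drawer images to Darwin Core.

Run with ``python examples/worked_example.py``.  Everything happens in a
temporary directory with an in-memory database; nothing is left behind.
"""

import pathlib
import tempfile

from colldigi.analytics import ThreePointTiming, project_estimate
from colldigi.datastore import Store
from colldigi.georeferencing import build_triage_queue, set_georeference
from colldigi.ingest import MockCMS, publish_occurrences, run_full_export, year_from_rule
from colldigi.normalization import assign_variant, dedup_report
from colldigi.pipeline import process_batch, rename_for_barcode
from colldigi.synthetic import DEFAULT_SITE_POOL, GenerationConfig, generate_collection
from colldigi.transcription import allocate_records, transcribe_batch

# 1. Generate a ground-truthed synthetic collection: 48 specimens across
#    three drawers, with 10% of the barcodes deliberately damaged.
root = pathlib.Path(tempfile.mkdtemp()) / "dropoff"
cfg = GenerationConfig(n_drawers=3, specimens_per_drawer=16, seed=7, misread_rate=0.1)
manifest = generate_collection(cfg, root)

store = Store()  # in-memory; pass a path for a persistent database
for name, roles in [("amy", {"transcriber"}), ("ben", {"georeferencer"}),
                    ("cat", {"data_manager"}), ("dan", {"scrutineer"})]:
    store.add_user(name, roles)

# 2. Overnight batch: crop labels, decode barcodes, rename, create records.
report = process_batch(store, root)
print(f"frames seen        : {report.n_images_seen}")
print(f"specimens created  : {report.n_specimens_created}")
print(f"barcode failures   : {report.n_barcode_failures}")

# 3. Manual barcode correction for the failures (here from the generator's
#    manifest, standing in for a person reading the printed code).
by_file = {str(root / r["file"]): r["barcode"] for _, r in manifest.iterrows()}
for s in store.all_specimens():
    if "barcode_unread" in (s["flags"] or ""):
        full = [i for i in store.images_for(s["id"]) if i["role"] == "full"][0]
        rename_for_barcode(store, s["id"], by_file[full["path"]], "amy")

# 4. Batch transcription from CSV (the manifest plays the transcriber).
csv = root / "transcription.csv"
manifest.rename(columns={"site_variant_used": "site_verbatim",
                         "collector": "collectors"})[
    ["barcode", "site_verbatim", "date_verbatim", "collectors"]].to_csv(csv, index=False)
allocate_records(store, "cat", "amy", [s["id"] for s in store.all_specimens()])
n = transcribe_batch(store, "amy", csv)
print(f"transcribed        : {n}")

# 5. Normalisation: assign each verbatim variant to its master.
truth = {v: m for m, vs, _ in DEFAULT_SITE_POOL for v in vs}
for v in sorted(set(manifest["site_variant_used"])):
    assign_variant(store, "ben", "site", v, truth[v])
for t in sorted(set(manifest["taxon"])):
    assign_variant(store, "dan", "taxon", t, t)
rep = dedup_report(store, "site")
print(f"site variants      : {rep.n_variants} -> {rep.n_masters} masters "
      f"({rep.pct_reduction}% reduction)")

# 6. Georeferencing, triaged by payoff.
queue = build_triage_queue(store)
print(f"triage high-freq   : {len(queue.stage_entries('high_frequency'))} sites "
      f"covering {queue.coverage_fraction():.0%} of specimens")
coords = {"Reading, Berkshire, UK, Europe": (51.455, -0.978, 2000),
          "Box Hill, Surrey, UK, Europe": (51.254, -0.327, 1000),
          "Wicken Fen, Cambridgeshire, UK, Europe": (52.309, 0.290, 1500),
          "Folkestone, Kent, UK, Europe": (51.081, 1.169, 2000),
          "New Forest, Hampshire, UK, Europe": (50.870, -1.630, 8000),
          "Aviemore, Highland, UK, Europe": (57.195, -3.826, 3000)}
for m in sorted({truth[v] for v in manifest["site_variant_used"]}):
    set_georeference(store, "ben", m, *coords[m])

# 7. Dependency-ordered CMS round trip, then Darwin Core publication under
#    a collected-since-1960 embargo.
cms = MockCMS()
cms.register_existing("locations", sorted(manifest["drawer"].unique()))
counts = run_full_export(store, cms)
print(f"CMS round trip     : {counts}")
occ = publish_occurrences(store, [year_from_rule(1960)])
print(f"published          : {len(occ)} occurrence rows (post-1959 embargoed)")
print()
print(occ[["occurrenceID", "verbatimLocality", "locality", "eventDate"]]
      .head(5).to_string(index=False))
print()

# 8. Throughput estimation from the published butterfly stage timings.
timings = {"preparation": ThreePointTiming(0.13, 0.85, 1.50),
           "imaging": ThreePointTiming(0.47, 0.93, 1.88),
           "transcription": ThreePointTiming(0.05, 0.53, 1.14)}
est = project_estimate(timings)
print(f"per-specimen estimate: {est.total} min  stage shares: {est.shares}")
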