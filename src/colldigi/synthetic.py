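"""Ground-truthed synthetic specimen collection.

Generates a folder tree of photograph-like JPEGs in the production layout
``Drawer##/Taxonomic name/*.jpg`` together with a manifest recording the
truth behind every file, so the whole pipeline can be exercised and scored
without museum data.

Each image emulates a pinned-insect unit-tray photograph: a neutral grey
stage occupying the left three quarters of the frame with a dark specimen
silhouette, and a light label panel on the right quarter carrying the
typed verbatim label text (site, date, collector) and a DataMatrix barcode.
The generator controls the statistical structure the downstream modules
care about:

* a weighted pool of site *masters*, each rendered through several verbatim
  *variant* spellings (the "Reading" / "Reading, Berks" / "Redding" effect),
* a configurable fraction of deliberately damaged barcodes (misreads), of
  labels with no barcode at all, and of double-sided labels photographed
  from both sides (a second ``*_b.jpg`` file).

The same seed always yields a byte-identical manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import datamatrix
from .config import JPEG_QUALITY, format_barcode

_ROMAN = ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x", "xi", "xii"]
_DAYS_IN_MONTH = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]

# A small gazetteer of British site masters with their typical label variants.
DEFAULT_SITE_POOL: list[tuple[str, list[str], float]] = [
    ("Reading, Berkshire, UK, Europe", ["Reading", "Reading, Berks", "Redding"], 6.0),
    ("Box Hill, Surrey, UK, Europe", ["Box Hill", "Box Hill, Surrey"], 4.0),
    ("Wicken Fen, Cambridgeshire, UK, Europe", ["Wicken Fen", "Wicken"], 3.0),
    ("Folkestone, Kent, UK, Europe", ["Folkestone", "Folkestone, Kent"], 2.0),
    ("New Forest, Hampshire, UK, Europe", ["New Forest", "New Forest, Hants"], 2.0),
    ("Aviemore, Highland, UK, Europe", ["Aviemore"], 1.0),
]

DEFAULT_TAXA = [
    "Hesperia comma",
    "Polyommatus icarus",
    "Aglais urticae",
    "Pieris brassicae",
]

DEFAULT_COLLECTORS = ["A. Smith", "E. B. Ford", "L. W. Newman", "M. Jones"]


@dataclass
class GenerationConfig:
    """Study conditions for one synthetic collection."""

    n_drawers: int = 2
    taxa: list[str] = field(default_factory=lambda: list(DEFAULT_TAXA))
    specimens_per_drawer: int = 8
    site_pool: list[tuple[str, list[str], float]] = field(
        default_factory=lambda: list(DEFAULT_SITE_POOL)
    )
    collector_pool: list[str] = field(default_factory=lambda: list(DEFAULT_COLLECTORS))
    date_range: tuple[int, int] = (1890, 1970)
    misread_rate: float = 0.0
    missing_barcode_rate: float = 0.0
    double_sided_fraction: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = (2400, 1600)  # (width, height)
    barcode_prefix: str = "NHMUK"
    barcode_start: int = 10_000_001

    def validate(self) -> None:
        for name in ("misread_rate", "missing_barcode_rate", "double_sided_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(w <= 0 for _, _, w in self.site_pool):
            raise ValueError("site pool weights must be positive")
        if self.n_drawers < 1 or self.specimens_per_drawer < 1:
            raise ValueError("need at least one drawer and one specimen per drawer")

    @property
    def n_specimens(self) -> int:
        return self.n_drawers * self.specimens_per_drawer


def _verbatim_date(rng: np.random.Generator, y0: int, y1: int) -> tuple[str, str, str]:
    """Pick a label-style date; returns (verbatim, iso_start, iso_end)."""
    year = int(rng.integers(y0, y1 + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, _DAYS_IN_MONTH[month - 1] + 1))
    style = rng.choice(["full_roman", "full_arabic", "month_year", "year"])
    iso = f"{year:04d}-{month:02d}-{day:02d}"
    if style == "full_roman":
        return f"{day}.{_ROMAN[month - 1]}.{year}", iso, iso
    if style == "full_arabic":
        return f"{day}.{month}.{year}", iso, iso
    if style == "month_year":
        last = _DAYS_IN_MONTH[month - 1]
        return (
            f"{_ROMAN[month - 1]}.{year}",
            f"{year:04d}-{month:02d}-01",
            f"{year:04d}-{month:02d}-{last:02d}",
        )
    return str(year), f"{year:04d}-01-01", f"{year:04d}-12-31"


def _render_image(
    cfg: GenerationConfig,
    rng: np.random.Generator,
    barcode: str | None,
    corrupted: bool,
    lines: list[str],
    back: bool = False,
) -> Image.Image:
    w, h = cfg.image_size
    arr = np.full((h, w), 190, dtype=np.uint8)  # grey stage
    panel_x = w - w // 4
    arr[:, panel_x:] = 245  # light label panel
    img = Image.fromarray(arr)
    draw = ImageDraw.Draw(img)
    if not back:
        # crude pinned-specimen silhouette on the stage
        cx = int(rng.integers(int(w * 0.2), int(w * 0.5)))
        cy = int(rng.integers(int(h * 0.3), int(h * 0.7)))
        rx, ry = int(w * 0.12), int(h * 0.18)
        draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], fill=60)
        draw.line([cx, cy - int(ry * 1.4), cx, cy + int(ry * 1.4)], fill=40, width=6)
    # typed label text, high-contrast so decoding is limited only by the
    # deliberate corruption below
    tx = panel_x + 20
    ty = 60
    for line in lines:
        draw.text((tx, ty), line, fill=10)
        ty += 40
    if barcode is not None:
        sym = datamatrix.render(barcode, module_px=10)
        sh, sw = sym.shape
        sy = h - sh - 120
        sx = panel_x + (w // 4 - sw) // 2
        out = np.asarray(img).copy()
        out[sy : sy + sh, sx : sx + sw] = sym
        if corrupted:
            # obliterate a random rectangle covering ~30% of the symbol
            side = 0.55
            rh, rw = int(sh * side), int(sw * side)
            r0 = sy + int(rng.integers(0, sh - rh + 1))
            c0 = sx + int(rng.integers(0, sw - rw + 1))
            out[r0 : r0 + rh, c0 : c0 + rw] = 245
        img = Image.fromarray(out)
    return img


def generate_collection(cfg: GenerationConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the image tree under ``out_dir``; return the manifest.

    The manifest (one row per specimen) is also written to
    ``out_dir/manifest.csv``.  The first ``len(variants)`` specimens cycle
    through every variant spelling once, guaranteeing that each configured
    verbatim string occurs in the output; the remainder draw sites by
    weight.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # flatten (master, variant) pairs; weight shared equally among a master's
    # variants
    pairs: list[tuple[str, str]] = []
    weights: list[float] = []
    for master, variants, wgt in cfg.site_pool:
        for v in variants:
            pairs.append((master, v))
            weights.append(wgt / len(variants))
    probs = np.asarray(weights) / sum(weights)

    rows = []
    counter = cfg.barcode_start
    for i in range(cfg.n_specimens):
        drawer_i = i // cfg.specimens_per_drawer
        drawer = f"Drawer{drawer_i + 1:02d}"
        taxon = cfg.taxa[drawer_i % len(cfg.taxa)]
        if i < len(pairs):
            master, variant = pairs[i]  # coverage guarantee
        else:
            master, variant = pairs[int(rng.choice(len(pairs), p=probs))]
        collector = str(rng.choice(cfg.collector_pool))
        date_verbatim, date_start, date_end = _verbatim_date(rng, *cfg.date_range)
        barcode = format_barcode(counter, cfg.barcode_prefix, 9)
        counter += 1
        missing = bool(rng.random() < cfg.missing_barcode_rate)
        corrupted = bool(not missing and rng.random() < cfg.misread_rate)
        double = bool(rng.random() < cfg.double_sided_fraction)

        folder = out / drawer / taxon
        folder.mkdir(parents=True, exist_ok=True)
        fname = f"img{i + 1:05d}.jpg"
        lines = [variant, date_verbatim, collector]
        img = _render_image(cfg, rng, None if missing else barcode, corrupted, lines)
        img.save(folder / fname, format="JPEG", quality=JPEG_QUALITY)
        if double:
            det_year = int(rng.integers(cfg.date_range[0], cfg.date_range[1] + 1))
            back_lines = [f"det. {det_year}", f"ex coll. {collector}"]
            back = _render_image(cfg, rng, None, False, back_lines, back=True)
            back.save(folder / f"img{i + 1:05d}_b.jpg", format="JPEG", quality=JPEG_QUALITY)

        rows.append(
            {
                "barcode": barcode,
                "drawer": drawer,
                "taxon": taxon,
                "site_master": master,
                "site_variant_used": variant,
                "collector": collector,
                "date_verbatim": date_verbatim,
                "date_start": date_start,
                "date_end": date_end,
                "file": f"{drawer}/{taxon}/{fname}",
                "corrupted_barcode": corrupted,
                "missing_barcode": missing,
                "double_sided": double,
            }
        )

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False, encoding="utf-8")
    return manifest


def emulate_dedup_profile(
    n_variants: int, n_masters: int, n_specimens: int, seed: int = 0
) -> list[tuple[str, list[str], float]]:
    """Build a site pool with a prescribed deduplication structure.

    A collection generated from the returned pool (with at least
    ``n_specimens`` specimens) contains exactly ``n_variants`` distinct
    verbatim site strings mapping to ``n_masters`` ground-truth masters, so
    the normalisation report's percent reduction is fixed by construction.
    Master weights follow a Zipf-like profile so a handful of sites dominate,
    as in real collections.
    """
    if n_masters < 1:
        raise ValueError("need at least one master")
    if not (n_masters <= n_variants <= n_specimens):
        raise ValueError(
            f"need n_masters <= n_variants <= n_specimens, got "
            f"({n_masters}, {n_variants}, {n_specimens})"
        )
    rng = np.random.default_rng(seed)
    # distribute variants over masters: one each, extras at random
    counts = np.ones(n_masters, dtype=int)
    for _ in range(n_variants - n_masters):
        counts[int(rng.integers(0, n_masters))] += 1
    pool = []
    for m in range(n_masters):
        master = f"Site {m + 1:04d}, Shire, UK, Europe"
        variants = [f"Site {m + 1:04d}"]
        for v in range(1, counts[m]):
            variants.append(f"Site {m + 1:04d} var{v}")
        pool.append((master, variants, 1.0 / (m + 1)))  # Zipf-ish weights
    return pool
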