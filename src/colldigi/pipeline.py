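"""The overnight batch: crop labels, read barcodes, rename, create records.

Walks an image drop-off tree laid out as ``Drawer##/Taxonomic name/*.jpg``,
and for each new photograph:

1. crops the rightmost quarter of the frame (the label panel), resizes it to
   the fixed 800x1219 label size and writes it alongside the original with a
   ``_label`` suffix;
2. decodes the DataMatrix barcode from the original-resolution crop (falling
   back to a sharpened, half-scaled copy, which helps on soft focus);
3. renames both files to ``<barcode>.jpg`` / ``<barcode>_label.jpg`` -- on a
   decode failure the original name is retained and the record is flagged
   for manual barcode correction;
4. creates the specimen record (drawer and taxon read from the folder path)
   and the linked image records.

Processing is idempotent: files are tracked by content hash, so re-running
over the same tree creates nothing new even after the renames.  Files named
``*_b.jpg`` are treated as the reverse side of the sibling image's labels
and attach a ``label_back`` crop to the same specimen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageFilter, ImageOps

from . import datamatrix
from .config import JPEG_QUALITY, LABEL_SIZE
from .datastore import ConflictError, Store, ValidationError

log = logging.getLogger(__name__)


class PathParseError(ValueError):
    """Image file not under the Drawer/Taxon folder convention."""


@dataclass
class BatchReport:
    """Counts and failures from one run over the drop-off tree."""

    n_images_seen: int = 0
    n_specimens_created: int = 0
    n_label_crops: int = 0
    n_barcode_failures: int = 0
    n_skipped_existing: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.failures, columns=["path", "reason"])


def parse_folder_path(path: str | Path, root: str | Path) -> tuple[str, str]:
    """Extract (drawer, taxon_name) from a file's position under ``root``.

    The first directory level below the root is the drawer, the second the
    taxon.  Deeper levels are ignored with a warning; files lying flat in
    the root (or one level down) cannot be attributed and raise
    :class:`PathParseError`.
    """
    rel = Path(path).resolve().relative_to(Path(root).resolve())
    parts = rel.parts
    if len(parts) < 3:
        raise PathParseError(f"{path}: expected Drawer/Taxon/file below root")
    if len(parts) > 3:
        log.warning("%s: ignoring %d extra folder level(s)", path, len(parts) - 3)
    return parts[0], parts[1]


def crop_label_region(image: Image.Image) -> Image.Image:
    """Rightmost quarter of the frame, resampled to the fixed label size.

    The crop width is ``max(1, width // 4)`` pixels; the result is resized
    (bicubic, no padding) to exactly 800x1219 regardless of the source
    aspect ratio.
    """
    w, h = image.size
    if w < 4:
        raise ValidationError(f"image too narrow to crop: width={w}")
    crop_w = max(1, w // 4)
    crop = image.crop((w - crop_w, 0, w, h))
    return crop.resize(LABEL_SIZE, Image.BICUBIC)


def _raw_label_crop(image: Image.Image) -> Image.Image:
    w, h = image.size
    crop_w = max(1, w // 4)
    return image.crop((w - crop_w, 0, w, h))


def decode_datamatrix(image: Image.Image) -> datamatrix.DecodeResult:
    """Read the barcode from a label crop, with a sharpen-and-downscale retry."""
    grey = image.convert("L")
    result = datamatrix.read_barcode(np.asarray(grey))
    if result.payload is None:
        small = grey.resize((max(1, grey.width // 2), max(1, grey.height // 2)), Image.BICUBIC)
        sharp = small.filter(ImageFilter.SHARPEN)
        result = datamatrix.read_barcode(np.asarray(sharp))
    return result


def _iter_images(root: Path):
    for p in sorted(root.rglob("*.jpg")):
        yield p


def process_batch(store: Store, root: str | Path, dry_run: bool = False) -> BatchReport:
    """Process every unprocessed image under ``root``; see module docstring."""
    root = Path(root)
    if not root.is_dir():
        raise ValidationError(f"no such folder: {root}")
    report = BatchReport()
    back_files: list[Path] = []
    for path in _iter_images(root):
        if path.stem.endswith("_label") or path.stem.endswith("_label_back"):
            continue
        if path.stem.endswith("_b"):
            back_files.append(path)
            continue
        report.n_images_seen += 1
        _process_one(store, root, path, report, dry_run)
    for path in back_files:
        report.n_images_seen += 1
        _process_back(store, root, path, report, dry_run)
    return report


def _open_upright(path: Path) -> Image.Image:
    img = Image.open(path)
    return ImageOps.exif_transpose(img)


def _process_one(
    store: Store, root: Path, path: Path, report: BatchReport, dry_run: bool
) -> None:
    file_hash = Store.content_hash(path)
    if store.is_processed(file_hash):
        report.n_skipped_existing += 1
        return
    try:
        drawer, taxon = parse_folder_path(path, root)
    except PathParseError as exc:
        report.failures.append((str(path), f"path: {exc}"))
        return
    try:
        img = _open_upright(path)
        img.load()
    except Exception as exc:  # corrupt file
        report.failures.append((str(path), f"unreadable: {exc}"))
        return

    raw_crop = _raw_label_crop(img)
    label_img = crop_label_region(img)
    decode = decode_datamatrix(raw_crop)
    if dry_run:
        return

    taxon_vid = store.ensure_variant("taxon", taxon)

    if decode.payload is None:
        # keep original filename; record exists but is flagged for manual
        # barcode correction during transcription
        label_path = path.with_name(path.stem + "_label.jpg")
        label_img.save(label_path, format="JPEG", quality=JPEG_QUALITY)
        report.n_label_crops += 1
        report.n_barcode_failures += 1
        report.failures.append((str(path), "barcode: no symbol decoded"))
        sid = store.create_specimen(None, drawer, taxon_vid, flags={"barcode_unread"})
        store.add_image(str(path), "full", img.width, img.height, sid)
        store.add_image(str(label_path), "label", *LABEL_SIZE, sid)
        store.mark_processed(file_hash, str(path), str(path), sid)
        return

    code = decode.payload
    existing = store.specimen_by_barcode(code)
    if existing is not None:
        # same barcode seen twice: flag both records, do not overwrite files
        store.add_flag(existing["id"], "for_scrutiny")
        label_path = path.with_name(path.stem + "_label.jpg")
        label_img.save(label_path, format="JPEG", quality=JPEG_QUALITY)
        report.n_label_crops += 1
        report.failures.append((str(path), f"barcode collision: {code}"))
        sid = store.create_specimen(None, drawer, taxon_vid, flags={"for_scrutiny"})
        store.add_image(str(path), "full", img.width, img.height, sid)
        store.add_image(str(label_path), "label", *LABEL_SIZE, sid)
        store.mark_processed(file_hash, str(path), str(path), sid)
        return

    new_full = path.with_name(f"{code}.jpg")
    new_label = path.with_name(f"{code}_label.jpg")
    label_img.save(new_label, format="JPEG", quality=JPEG_QUALITY)
    report.n_label_crops += 1
    path.rename(new_full)

    flags = {"two_barcodes"} if decode.n_symbols > 1 else set()
    sid = store.create_specimen(code, drawer, taxon_vid, flags=flags)
    store.add_image(str(new_full), "full", img.width, img.height, sid)
    store.add_image(str(new_label), "label", *LABEL_SIZE, sid)
    store.mark_processed(file_hash, str(new_full), str(path), sid)
    report.n_specimens_created += 1


def _process_back(
    store: Store, root: Path, path: Path, report: BatchReport, dry_run: bool
) -> None:
    """Attach the reverse-side label crop of ``X_b.jpg`` to X's specimen."""
    file_hash = Store.content_hash(path)
    if store.is_processed(file_hash):
        report.n_skipped_existing += 1
        return
    if dry_run:
        return
    base_stem = path.stem[:-2]
    orig = str(path.with_name(base_stem + ".jpg"))
    sid = store.specimen_for_original_path(orig)
    if sid is None:
        report.failures.append((str(path), "label back: no matching front image"))
        return
    try:
        img = _open_upright(path)
        img.load()
    except Exception as exc:
        report.failures.append((str(path), f"unreadable: {exc}"))
        return
    back_crop = crop_label_region(img)
    spec = store.specimen(sid)
    stem = spec["barcode"] if spec["barcode"] else base_stem
    back_path = path.with_name(f"{stem}_label_back.jpg")
    back_crop.save(back_path, format="JPEG", quality=JPEG_QUALITY)
    try:
        store.add_image(str(back_path), "label_back", *LABEL_SIZE, sid)
    except ConflictError as exc:
        report.failures.append((str(path), str(exc)))
        return
    store.mark_processed(file_hash, str(path))


def rename_for_barcode(store: Store, specimen_id: int, corrected_code: str, user: str) -> None:
    """Manually correct a misread barcode, renaming the image files.

    The filename/barcode correspondence is restored for every linked image;
    the previous code (if any) is discarded so it can never be re-issued.
    Correcting to the specimen's current code is a no-op; correcting to a
    code attached to another specimen is refused.
    """
    store.require_role(user, "transcriber")
    spec = store.specimen(specimen_id)
    old_code = spec["barcode"]
    if corrected_code == old_code:
        return
    other = store.specimen_by_barcode(corrected_code)
    if other is not None:
        raise ConflictError(
            f"barcode {corrected_code} already belongs to specimen {other['id']}"
        )
    state = store.barcode_state(corrected_code)
    if state in ("attached", "discarded"):
        raise ConflictError(f"barcode {corrected_code} is {state}")
    store.register_decoded_barcode(corrected_code)
    for img in store.images_for(specimen_id):
        old_path = Path(img["path"])
        suffix = {"full": "", "label": "_label", "label_back": "_label_back"}[img["role"]]
        new_path = old_path.with_name(f"{corrected_code}{suffix}.jpg")
        if old_path.exists() and old_path != new_path:
            old_path.rename(new_path)
        store.update_image_path(img["id"], str(new_path))
    # clear barcode first to free the UNIQUE slot, then attach the new code
    store.update_specimen(specimen_id, barcode=None)
    store.update_specimen(specimen_id, barcode=corrected_code)
    if old_code is not None:
        store.db.execute("UPDATE barcodes SET state='discarded' WHERE code=?", (old_code,))
        store.db.commit()
    flags = store.specimen_flags(specimen_id)
    flags.discard("barcode_unread")
    store.db.execute(
        "UPDATE specimens SET flags=? WHERE id=?", (",".join(sorted(flags)), specimen_id)
    )
    store.db.commit()
    store.audit(user, "rename_for_barcode", f"specimen {specimen_id}: {old_code} -> {corrected_code}")
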