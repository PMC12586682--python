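"""Synthetic sequence panels and packaged toy fixtures.

Everything here is synthetic: sequences are constructed stand-ins for the
assay's deposited amplicons and reference mitogenomes, built so the panel
reproduces the field situation — most species well separated, plus one pair
differing by exactly 4 nucleotides, one by exactly 12, and one by a single
nucleotide (the hardest case, where melt profiles nearly coincide).

Amplicons are built as forward primer + core + revcomp(reverse primer), so
in-silico PCR on the flanked "mitogenome" templates recovers them exactly at
the assay's 223 bp product length.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .amplicon import (
    DEFAULT_PRIMERS,
    AmpliconRecord,
    reverse_complement,
    write_fasta,
)
from .meltsim import MeltModelParams, make_labeled_dataset, save_manifest, write_runs_csv

__all__ = ["AMPLICON_LENGTH", "CLOSE_PAIR_DIFFS", "make_panel",
           "make_template", "make_fixtures"]

#: Product length of the assay, primer footprints included.
AMPLICON_LENGTH = 223

#: Designated nucleotide distances between the panel's close species pairs.
CLOSE_PAIR_DIFFS = {"four_nt": 4, "twelve_nt": 12, "one_nt": 1}

def _exact_gc_segment(rng: np.random.Generator, length: int,
                      gc_target: float) -> str:
    """Segment with exactly round(gc_target * length) G/C bases, shuffled."""
    n_gc = int(round(gc_target * length))
    strong = rng.choice(np.array(list("GC")), size=n_gc)
    weak = rng.choice(np.array(list("AT")), size=length - n_gc)
    seq = np.concatenate([strong, weak])
    rng.shuffle(seq)
    return "".join(seq)


def _random_core(rng: np.random.Generator, length: int, gc_target: float,
                 n_segments: int = 3) -> str:
    """Core built from segments of controlled GC, so every melting domain's
    Tm lands inside the melt window (clear of the normalization baselines)."""
    base, rem = divmod(length, n_segments)
    parts = []
    for i in range(n_segments):
        seg_len = base + (1 if i < rem else 0)
        gc = float(np.clip(gc_target + 0.06 * rng.standard_normal(), 0.50, 0.72))
        parts.append(_exact_gc_segment(rng, seg_len, gc))
    return "".join(parts)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` positions, always flipping the GC class
    (A/T -> G/C or vice versa) so each substitution shifts the domain Tm."""
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in positions:
        options = "GC" if chars[pos] in "AT" else "AT"
        chars[pos] = options[rng.integers(2)]
    return "".join(chars)


def make_panel(n_species: int = 10, seed: int = 0) -> list[AmpliconRecord]:
    """A synthetic species panel of 223 bp amplicons.

    Species 1/2 differ by exactly 4 nucleotides, species 3/4 by exactly 12,
    and species 5 differs from species 2 by exactly 1 (requires
    ``n_species >= 5``; smaller panels omit the later pairs).  GC content
    varies across species so melt signatures are sequence-determined.
    """
    if n_species < 2:
        raise ValueError("panel needs at least 2 species")
    rng = np.random.default_rng(seed)
    fwd = DEFAULT_PRIMERS.forward
    rev_site = reverse_complement(DEFAULT_PRIMERS.reverse)
    core_len = AMPLICON_LENGTH - len(fwd) - len(rev_site)

    def gc_signature(core: str) -> tuple[int, ...]:
        """G/C counts over the amplicon's three melting domains."""
        amp = fwd + core + rev_site
        base, rem = divmod(len(amp), 3)
        counts, pos = [], 0
        for d in range(3):
            seg_len = base + (1 if d < rem else 0)
            counts.append(sum(c in "GC" for c in amp[pos:pos + seg_len]))
            pos += seg_len
        return tuple(counts)

    cores: list[str] = []
    signatures: list[tuple[int, ...]] = []
    for i in range(n_species):
        if i == 1 and len(cores) >= 1:
            core = _mutate(rng, cores[0], CLOSE_PAIR_DIFFS["four_nt"])
        elif i == 3 and len(cores) >= 3:
            core = _mutate(rng, cores[2], CLOSE_PAIR_DIFFS["twelve_nt"])
        elif i == 4 and len(cores) >= 2:
            core = _mutate(rng, cores[1], CLOSE_PAIR_DIFFS["one_nt"])
        else:
            # distinct composition signatures for the non-designated species:
            # every random species keeps a clear melt-signature distance from
            # all others; only the designated pairs above are near-identical
            for _ in range(200):
                gc = 0.54 + 0.14 * rng.random()
                core = _random_core(rng, core_len, gc)
                sig = gc_signature(core)
                if all(sum(abs(a - b) for a, b in zip(sig, s)) >= 3
                       for s in signatures):
                    break
            else:
                raise RuntimeError("could not draw a distinct species signature")
        cores.append(core)
        signatures.append(gc_signature(core))

    return [
        AmpliconRecord(
            id=f"SYN{i + 1:03d}",
            sequence=fwd + core + rev_site,
            species_label=f"synthetic_species_{i + 1:02d}",
            role="amplicon",
        )
        for i, core in enumerate(cores)
    ]


def make_template(amplicon: AmpliconRecord, seed: int = 0,
                  flank_length: int = 400) -> AmpliconRecord:
    """Embed an amplicon in random flanks — a synthetic mitogenome stand-in."""
    rng = np.random.default_rng(seed)
    left = _random_core(rng, flank_length, 0.45)
    right = _random_core(rng, flank_length, 0.45)
    return AmpliconRecord(
        id=f"{amplicon.id}|template",
        sequence=left + amplicon.sequence + right,
        species_label=amplicon.species_label,
        role="template",
    )


def make_fixtures(out_dir: str | Path, seed: int = 7,
                  n_species: int = 10, n_per_species: int = 12) -> dict:
    """Write the packaged toy fixture set and its regression checksums.

    Produces a synthetic panel FASTA, pre-simulated runs (long CSV), a run
    manifest (JSON) and a checksum file; regeneration with the same seed
    reproduces every byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = make_panel(n_species, seed)
    fasta_path = out_dir / "synthetic_panel.fasta"
    write_fasta(panel, fasta_path)

    runs, manifest = make_labeled_dataset(
        panel, n_per_species, MeltModelParams(), master_seed=seed,
        weak_fraction=0.165)
    runs_path = out_dir / "runs.csv"
    write_runs_csv(runs, runs_path)
    manifest_path = out_dir / "manifest.json"
    save_manifest(manifest, manifest_path)

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in (fasta_path, runs_path, manifest_path)
    }
    (out_dir / "checksums.json").write_text(json.dumps(checksums, indent=1))
    return checksums
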