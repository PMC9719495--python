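"""Synthetic study generator.

Emulates the field design this pipeline targets: paired burnt/unburnt patches
in a frequently burnt pine savanna, half the pairs near overstory pines, with a
litter and a soil sample per plot (30 pairs -> 60 plots -> 120 samples, with an
option to drop one sample so 119 remain, mirroring the single failed library).

Family-level read counts are negative binomial with multiplicative substrate,
fire, and substrate-by-fire effects on the family mean; ESV counts partition
each family total multinomially with fixed within-family simplex weights, so
the family-level generative means are exactly the stated model. Index reads
(the demultiplexing fixture) are simulated with a uniform per-base substitution
rate and Phred qualities consistent with that rate; no biological read content
is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .errors import BarcodeError, DegenerateInputError, InvalidDesignError, InvalidSpecError

SUBSTRATES = ("litter", "soil")
FIRES = ("burnt", "unburnt")
CELLS = ("burnt-litter", "unburnt-litter", "burnt-soil", "unburnt-soil")

#: ratio of cell means beyond which a family counts as a true specialist
SPECIALIST_RATIO = 1.5


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(
    n_pairs: int = 30,
    pine_split: float = 0.5,
    seed: int = 0,
    drop_one: bool = False,
) -> pd.DataFrame:
    """Sample metadata for the paired burnt/unburnt, litter/soil layout.

    Returns one row per sample with columns ``sample_id, plot, pair, fire,
    substrate, pine``. Every burnt plot has exactly one unburnt partner with
    the same pine status. Deterministic under a fixed seed.
    """
    if not isinstance(n_pairs, (int, np.integer)) or isinstance(n_pairs, bool) or n_pairs < 1:
        raise InvalidDesignError(f"n_pairs must be a positive integer, got {n_pairs!r}")
    if not 0.0 <= pine_split <= 1.0:
        raise InvalidDesignError(f"pine_split must lie in [0, 1], got {pine_split}")

    rng = stage_rng(seed, "design")
    n_near = int(round(pine_split * n_pairs))
    near_pairs = set(rng.choice(n_pairs, size=n_near, replace=False).tolist())

    rows = []
    for pair in range(1, n_pairs + 1):
        pine = "near" if (pair - 1) in near_pairs else "away"
        for fire in FIRES:
            plot = f"P{pair:02d}{'B' if fire == 'burnt' else 'U'}"
            for substrate in SUBSTRATES:
                rows.append(
                    {
                        "sample_id": f"{plot}_{substrate[0].upper()}",
                        "plot": plot,
                        "pair": f"pair{pair:02d}",
                        "fire": fire,
                        "substrate": substrate,
                        "pine": pine,
                    }
                )
    meta = pd.DataFrame(rows)
    if drop_one:
        # mirror the one failed library: drop a single sample, chosen
        # deterministically from the design substream
        drop = int(rng.integers(len(meta)))
        meta = meta.drop(index=drop).reset_index(drop=True)
    return meta


# ---------------------------------------------------------------------------
# effect specification and ground truth
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Planted family-level effects for the count generator.

    Fold changes are multiplicative on the family mean: ``substrate_effect``
    applies to litter samples (>1 favours litter), ``fire_effect`` to burnt
    samples, and ``interaction_effect`` to the single substrate-by-fire cell
    named in ``interaction_cell`` for that family.
    """

    baselines: np.ndarray
    substrate_effect: np.ndarray
    fire_effect: np.ndarray
    interaction_effect: np.ndarray
    interaction_cell: np.ndarray  # one of CELLS or "" per family
    dispersion: float = 30.0
    library_size_mean: float = 28_000.0
    esvs_per_family: int = 12
    family_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.baselines = np.asarray(self.baselines, dtype=float)
        n = self.baselines.size
        self.substrate_effect = np.broadcast_to(
            np.asarray(self.substrate_effect, dtype=float), (n,)
        ).copy()
        self.fire_effect = np.broadcast_to(np.asarray(self.fire_effect, dtype=float), (n,)).copy()
        self.interaction_effect = np.broadcast_to(
            np.asarray(self.interaction_effect, dtype=float), (n,)
        ).copy()
        self.interaction_cell = np.broadcast_to(
            np.asarray(self.interaction_cell, dtype=object), (n,)
        ).copy()
        if not np.isclose(self.baselines.sum(), 1.0):
            raise InvalidSpecError("family baselines must sum to 1")
        for name in ("substrate_effect", "fire_effect", "interaction_effect"):
            if np.any(getattr(self, name) <= 0):
                raise InvalidSpecError(f"{name} fold-changes must be > 0")
        if not np.all(np.asarray(self.dispersion) > 0):
            raise InvalidSpecError("negative-binomial dispersion must be > 0")
        if not self.family_names:
            self.family_names = [f"Family{i:03d}" for i in range(n)]
        bad = {c for c in self.interaction_cell if c not in CELLS and c != ""}
        if bad:
            raise InvalidSpecError(f"unknown interaction cells: {sorted(bad)}")

    @property
    def n_families(self) -> int:
        return self.baselines.size

    def cell_means(self, library_size: float | None = None) -> pd.DataFrame:
        """Expected family mean reads in each substrate-by-fire cell."""
        lib = self.library_size_mean if library_size is None else library_size
        out = {}
        for cell in CELLS:
            fire, substrate = cell.split("-")
            mult = np.ones(self.n_families)
            if substrate == "litter":
                mult *= self.substrate_effect
            if fire == "burnt":
                mult *= self.fire_effect
            mult = np.where(self.interaction_cell == cell, mult * self.interaction_effect, mult)
            out[cell] = lib * self.baselines * mult
        return pd.DataFrame(out, index=self.family_names)

    def true_labels(self) -> pd.Series:
        """Ground-truth specialist label per family (ratio rule on cell means)."""
        means = self.cell_means()
        labels = []
        r = SPECIALIST_RATIO
        for fam in means.index:
            m = means.loc[fam]
            litter = m[["burnt-litter", "unburnt-litter"]]
            soil = m[["burnt-soil", "unburnt-soil"]]
            burnt = m[["burnt-litter", "burnt-soil"]]
            unburnt = m[["unburnt-litter", "unburnt-soil"]]
            if litter.min() > r * soil.max():
                labels.append("litter")
            elif soil.min() > r * litter.max():
                labels.append("soil")
            elif burnt.min() > r * unburnt.max():
                labels.append("fire")
            else:
                single = [c for c in CELLS if m[c] > r * m.drop(c).max()]
                labels.append(single[0] if single else "none")
        return pd.Series(labels, index=means.index, name="true_label")

    @classmethod
    def study_default(
        cls,
        n_families: int = 83,
        fold: float = 3.0,
        dispersion: float = 30.0,
        library_size_mean: float = 28_000.0,
        esvs_per_family: int = 12,
    ) -> "EffectSpec":
        """The default study conditions: 83 families, 10 planted specialists.

        Baselines follow a gentle power-law rank-abundance curve; the ten
        effect families (3 litter, 3 soil, 2 fire, 2 single-cell) sit at
        spread abundance ranks so recovery is not an artifact of dominance.
        The dispersion default makes treatments explain roughly the share of
        community variance the statistic was designed around (~60%).
        """
        w = (np.arange(1, n_families + 1)) ** -0.3
        baselines = w / w.sum()
        sub = np.ones(n_families)
        fire = np.ones(n_families)
        inter = np.ones(n_families)
        cell = np.array([""] * n_families, dtype=object)
        step = max(n_families // 11, 1)
        idx = [min(2 + k * step, n_families - 1) for k in range(10)]
        sub[idx[0]] = sub[idx[1]] = sub[idx[2]] = fold          # litter specialists
        sub[idx[3]] = sub[idx[4]] = sub[idx[5]] = 1.0 / fold    # soil specialists
        fire[idx[6]] = fire[idx[7]] = fold                      # fire specialists
        inter[idx[8]] = fold
        cell[idx[8]] = "burnt-litter"
        inter[idx[9]] = fold
        cell[idx[9]] = "unburnt-soil"
        return cls(
            baselines=baselines,
            substrate_effect=sub,
            fire_effect=fire,
            interaction_effect=inter,
            interaction_cell=cell,
            dispersion=dispersion,
            library_size_mean=library_size_mean,
            esvs_per_family=esvs_per_family,
        )


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(
    design: pd.DataFrame,
    effect_spec: EffectSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """ESV count table + taxonomy map + ground truth for a design.

    Family totals per sample are negative binomial with mean
    ``library_size * baseline * fold-changes`` and gamma-Poisson dispersion
    ``k`` (variance mu + mu^2/k); ESV counts split each family total
    multinomially with fixed simplex weights.
    """
    if effect_spec.library_size_mean <= 0:
        raise DegenerateInputError("library_size_mean must be > 0 (all-zero table)")
    rng = stage_rng(seed, "counts")
    wrng = stage_rng(seed, "esv_weights")

    n_fam = effect_spec.n_families
    n_esv = effect_spec.esvs_per_family
    # fixed within-family ESV simplex weights (skewed, as real ESV tables are)
    esv_w = wrng.dirichlet(np.full(n_esv, 0.3), size=n_fam)

    cell_means = effect_spec.cell_means()
    k = float(effect_spec.dispersion)

    cells = design["fire"].str.cat(design["substrate"], sep="-").to_numpy()
    n_samp = len(design)
    fam_counts = np.zeros((n_samp, n_fam), dtype=np.int64)
    for cell in CELLS:
        rows = np.flatnonzero(cells == cell)
        if rows.size == 0:
            continue
        mu = cell_means[cell].to_numpy()[None, :]
        lam = rng.gamma(k, mu / k, size=(rows.size, n_fam))
        fam_counts[rows] = rng.poisson(lam)

    esv_counts = np.zeros((n_samp, n_fam * n_esv), dtype=np.int64)
    for f in range(n_fam):
        block = np.vstack([rng.multinomial(t, esv_w[f]) for t in fam_counts[:, f]])
        esv_counts[:, f * n_esv : (f + 1) * n_esv] = block

    esv_ids = [f"ESV{f * n_esv + e:05d}" for f in range(n_fam) for e in range(n_esv)]
    counts = pd.DataFrame(esv_counts, index=design["sample_id"].to_numpy(), columns=esv_ids)
    counts.index.name = "sample_id"

    # higher ranks group *scrambled* families (fixed coprime shuffle), so a
    # family-level effect dilutes among unrelated families when aggregated up
    shuf = [(f * 37) % n_fam for f in range(n_fam)]
    taxonomy = pd.DataFrame(
        {
            "esv_id": esv_ids,
            "kingdom": "Bacteria",
            "phylum": [f"Phylum{shuf[f] // 16:02d}" for f in range(n_fam) for _ in range(n_esv)],
            "class": [f"Class{shuf[f] // 8:02d}" for f in range(n_fam) for _ in range(n_esv)],
            "order": [f"Order{shuf[f] // 4:02d}" for f in range(n_fam) for _ in range(n_esv)],
            "family": [effect_spec.family_names[f] for f in range(n_fam) for _ in range(n_esv)],
            "genus": [
                f"Genus{f:03d}_{e % 3}" for f in range(n_fam) for e in range(n_esv)
            ],
        }
    )

    truth = {
        "family_labels": effect_spec.true_labels(),
        "esv_family": pd.Series(
            [effect_spec.family_names[f] for f in range(n_fam) for _ in range(n_esv)],
            index=esv_ids,
            name="family",
        ),
        "cell_means": cell_means,
    }
    return counts, taxonomy, truth


# ---------------------------------------------------------------------------
# index reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def make_barcodes(sample_ids, length: int = 12, seed: int = 0, dual: bool = False) -> pd.DataFrame:
    """Random unique index sequences for a set of samples."""
    rng = stage_rng(seed, "barcodes")
    seen: set[tuple] = set()
    rows = []
    for sid in sample_ids:
        while True:
            i1 = "".join(rng.choice(_BASES, size=length))
            i2 = "".join(rng.choice(_BASES, size=length)) if dual else None
            key = (i1, i2)
            if key not in seen:
                seen.add(key)
                break
        rows.append({"sample_id": sid, "index1": i1, **({"index2": i2} if dual else {})})
    return pd.DataFrame(rows)


def _error_to_qual(e: float) -> str:
    q = 40 if e <= 0 else int(round(-10.0 * np.log10(max(e, 1e-4))))
    return chr(33 + int(np.clip(q, 2, 40)))


def generate_index_reads(
    design: pd.DataFrame,
    barcode_set: pd.DataFrame,
    per_base_error: float = 0.001,
    read_count: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated index reads with per-read true sample of origin.

    Each read's origin is uniform over samples; every index base is substituted
    with probability ``per_base_error`` (to one of the three other bases) and
    gets the Phred quality matching that rate. Returns ``(reads, truth)`` where
    ``reads`` has columns read_id, index1, qual1[, index2, qual2].
    """
    if not 0.0 <= per_base_error < 0.75:
        raise InvalidSpecError("per_base_error must lie in [0, 0.75)")
    _validate_barcodes(barcode_set)
    rng = stage_rng(seed, "index_reads")

    samp = barcode_set.set_index("sample_id")
    sample_ids = [s for s in design["sample_id"] if s in samp.index]
    if not sample_ids:
        raise InvalidDesignError("barcode set shares no samples with the design")
    dual = "index2" in samp.columns

    origin = rng.choice(len(sample_ids), size=read_count)
    qual = _error_to_qual(per_base_error)

    def _mutate(seqs: np.ndarray) -> np.ndarray:
        arr = np.array([list(s) for s in seqs])
        hit = rng.random(arr.shape) < per_base_error
        if hit.any():
            # substitute to a uniformly random *different* base
            shift = rng.integers(1, 4, size=hit.sum())
            base_idx = np.searchsorted(_BASES, arr[hit])
            arr[hit] = _BASES[(base_idx + shift) % 4]
        return np.array(["".join(r) for r in arr])

    i1_true = samp["index1"].to_numpy()[
        [samp.index.get_loc(sample_ids[o]) for o in origin]
    ]
    reads = pd.DataFrame(
        {
            "read_id": [f"read{r:06d}" for r in range(read_count)],
            "index1": _mutate(i1_true),
            "qual1": qual * len(samp["index1"].iloc[0]),
        }
    )
    if dual:
        i2_true = samp["index2"].to_numpy()[
            [samp.index.get_loc(sample_ids[o]) for o in origin]
        ]
        reads["index2"] = _mutate(i2_true)
        reads["qual2"] = qual * len(samp["index2"].iloc[0])

    truth = pd.DataFrame(
        {"read_id": reads["read_id"], "true_sample": [sample_ids[o] for o in origin]}
    )
    return reads, truth


def generate_control_reads(
    barcode_set: pd.DataFrame,
    n_reads: int = 500,
    n_mismatch: tuple = (2, 3),
    per_base_error: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Known-spurious control reads for threshold calibration.

    Each control takes a real barcode, substitutes exactly 2-3 positions, and
    carries uniformly low qualities (high error probability) - the "similar
    barcode, very high error" reads used to calibrate the rejection threshold.
    """
    _validate_barcodes(barcode_set)
    rng = stage_rng(seed, "index_reads")
    bcs = barcode_set["index1"].to_numpy()
    L = len(bcs[0])
    qual = _error_to_qual(per_base_error) * L
    rows = []
    for r in range(n_reads):
        seq = np.array(list(bcs[rng.integers(len(bcs))]))
        k = int(rng.integers(n_mismatch[0], n_mismatch[1] + 1))
        pos = rng.choice(L, size=k, replace=False)
        shift = rng.integers(1, 4, size=k)
        base_idx = np.searchsorted(_BASES, seq[pos])
        seq[pos] = _BASES[(base_idx + shift) % 4]
        rows.append({"read_id": f"ctrl{r:04d}", "index1": "".join(seq), "qual1": qual})
    return pd.DataFrame(rows)


def _validate_barcodes(barcode_set: pd.DataFrame) -> None:
    if barcode_set is None or len(barcode_set) == 0:
        raise BarcodeError("empty barcode set")
    cols = ["index1"] + (["index2"] if "index2" in barcode_set.columns else [])
    keys = barcode_set[cols].agg("".join, axis=1)
    if keys.duplicated().any():
        dup = barcode_set.loc[keys.duplicated(), "sample_id"].tolist()
        raise BarcodeError(f"duplicate barcodes for samples {dup}")
    for c in cols:
        if barcode_set[c].str.len().nunique() != 1:
            raise BarcodeError(f"{c} sequences differ in length")
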