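"""Synthetic mini-snowball association data with planted semantic components.

The generator emulates a study design in which each participant produces
``n_level1`` free associates to a focal cue ("risk") and then ``n_level2``
associates to each of those level-1 responses — 30 responses per participant
under the default 5 + 5x5 design.  Words live in K planted components; a
participant's propensity to retrieve from each component is a softmax of
demographic effects plus individual heterogeneity, and level-2 responses stay
inside the eliciting word's home component except for a controllable leakage
probability.  Self-report risk ratings are generated as a linear function of
the participant's component propensities plus noise, so that downstream
regression and cross-validation machinery can be tested against known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .data import AssociationDataset, FOCAL_CUE

__all__ = [
    "GeneratorConfig",
    "generate_lexicon",
    "generate_participants",
    "generate_associations",
    "generate_survey",
    "generate_study",
    "SURVEY_ITEMS",
]

#: Survey item names: general risk propensity plus six life domains.
SURVEY_ITEMS = (
    "general",
    "driving",
    "financial",
    "recreational",
    "occupational",
    "health",
    "social",
)

N_AGE_BINS = 6
GENDERS = ("f", "m")


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig cannot describe a valid design."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults mirror the reference study design: 1205 participants balanced
    over six age bins and two genders, five level-1 associates and five
    level-2 associates per level-1 word (30 records per participant), and
    five planted components.

    Parameters
    ----------
    n_participants
        Sample size; quota-balanced over the 12 age-bin x gender cells.
    n_components
        Number K of planted semantic components (K >= 2).
    words_per_component
        Distinct word types per component.
    n_level1, n_level2
        Responses per cue at level 1 / per level-1 associate at level 2.
    leakage
        Probability in [0, 1] that a level-2 response is drawn from a
        component other than the eliciting word's home component.
    zipf_exponent
        Within-component word retrieval follows p(rank) ~ rank^-s; s = 0
        gives uniform retrieval.
    base_logits
        Per-component baseline retrieval logits (default: equal).
    age_effects
        Per-component slope of the retrieval logit over the age-bin
        index 1..6.
    gender_effects
        Per-component logit shift applied to female participants.
    propensity_sd
        SD of per-participant, per-component logit noise — individual
        heterogeneity in component propensities beyond demographics.
    sentiment_means, sentiment_sd
        Per-component mean word sentiment in [-1, 1] and the SD of word
        sentiment around it (scores are clipped to [-1, 1]).
    survey_loadings
        Per-component linear coefficients mapping component propensities
        to the latent risk-propensity score shared by all seven items.
    survey_intercepts
        Item-specific intercepts on the 0-10 rating scale.
    noise_sd
        SD of the Gaussian rating noise added before rounding/clipping.
    seed
        Seed for all randomness in the generator.
    """

    n_participants: int = 1205
    n_components: int = 5
    words_per_component: int = 40
    n_level1: int = 5
    n_level2: int = 5
    leakage: float = 0.1
    zipf_exponent: float = 1.0
    base_logits: tuple[float, ...] | None = None
    age_effects: tuple[float, ...] | None = None
    gender_effects: tuple[float, ...] | None = None
    propensity_sd: float = 1.0
    sentiment_means: tuple[float, ...] | None = None
    sentiment_sd: float = 0.15
    survey_loadings: tuple[float, ...] | None = None
    survey_intercepts: tuple[float, ...] = (5.0, 4.5, 4.0, 5.5, 5.0, 4.5, 5.0)
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ConfigurationError("n_components must be at least 2")
        for name in ("n_participants", "words_per_component", "n_level1", "n_level2"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0.0 <= self.leakage <= 1.0:
            raise ConfigurationError("leakage must lie in [0, 1]")
        if self.noise_sd < 0 or self.propensity_sd < 0 or self.sentiment_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.words_per_component < self.n_level2:
            raise ConfigurationError(
                "words_per_component must be >= n_level2 so that a cue page "
                "can be filled without repeats from a single component"
            )
        if len(self.survey_intercepts) != len(SURVEY_ITEMS):
            raise ConfigurationError(
                f"survey_intercepts must have {len(SURVEY_ITEMS)} entries"
            )
        for name in ("base_logits", "age_effects", "gender_effects",
                     "sentiment_means", "survey_loadings"):
            vec = getattr(self, name)
            if vec is not None and len(vec) != self.n_components:
                raise ConfigurationError(f"{name} must have n_components entries")
        sent = self._vector("sentiment_means", 0.0)
        if np.any(np.abs(sent) > 1.0):
            raise ConfigurationError("sentiment_means must lie in [-1, 1]")

    # -- resolved per-component parameter vectors ---------------------------

    def _vector(self, name: str, default: float) -> np.ndarray:
        vec = getattr(self, name)
        if vec is None:
            return np.full(self.n_components, default, dtype=float)
        return np.asarray(vec, dtype=float)

    @property
    def records_per_participant(self) -> int:
        return self.n_level1 * (1 + self.n_level2)

    def with_(self, **kw) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


def default_config(**kw) -> GeneratorConfig:
    """Study-design defaults with mildly structured planted effects.

    Components are planted with demographic shifts, graded sentiment, and
    survey loadings of mixed sign, so that every downstream analysis has a
    known non-null target by default.
    """
    base = dict(
        age_effects=(-0.1, 0.1, 0.0, 0.05, -0.05),
        gender_effects=(-0.3, 0.3, 0.0, 0.1, -0.1),
        sentiment_means=(0.8, -0.8, 0.3, -0.3, 0.0),
        survey_loadings=(4.0, -4.0, 2.0, -2.0, 0.0),
    )
    base.update(kw)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Lexicon


def generate_lexicon(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the planted lexicon.

    Returns a DataFrame indexed by word with columns ``component`` (home
    component index 0..K-1), ``rank`` (within-component retrieval rank,
    0 = most frequent) and ``sentiment`` (clipped to [-1, 1]).  Word tokens
    are synthetic (``w{component}_{rank}``) — natural-language realism is a
    non-goal.
    """
    rng = np.random.default_rng(_subseed(config.seed, "lexicon"))
    means = config._vector("sentiment_means", 0.0)
    rows = []
    for k in range(config.n_components):
        for r in range(config.words_per_component):
            score = means[k]
            if config.sentiment_sd > 0:
                score += rng.normal(0.0, config.sentiment_sd)
            rows.append((f"w{k}_{r}", k, r, float(np.clip(score, -1.0, 1.0))))
    lex = pd.DataFrame(rows, columns=["word", "component", "rank", "sentiment"])
    return lex.set_index("word")


# ---------------------------------------------------------------------------
# Participants


def generate_participants(config: GeneratorConfig) -> pd.DataFrame:
    """Quota-balanced participant table.

    Allocates participants to the 12 age-bin x gender cells as evenly as
    possible: every cell gets ``n // 12`` participants and the remainder is
    spread over cells chosen at random (without replacement), so cell sizes
    never differ by more than one.
    """
    n = config.n_participants
    if n < 12:
        warnings.warn(
            "fewer participants than age-bin x gender cells; quotas degenerate",
            stacklevel=2,
        )
    rng = np.random.default_rng(_subseed(config.seed, "participants"))
    cells = [(a, g) for a in range(1, N_AGE_BINS + 1) for g in GENDERS]
    counts = np.full(len(cells), n // len(cells), dtype=int)
    extra = rng.choice(len(cells), size=n % len(cells), replace=False)
    counts[extra] += 1
    records = []
    pid = 0
    for (age_bin, gender), c in zip(cells, counts):
        for _ in range(c):
            records.append((f"p{pid:05d}", age_bin, gender))
            pid += 1
    df = pd.DataFrame(records, columns=["participant_id", "age_bin", "gender"])
    return df.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Associations


def component_propensities(
    participants: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Per-participant softmax propensity over components.

    logit_k = base_k + age_effect_k * age_bin + gender_effect_k * 1[female]
              + Normal(0, propensity_sd)
    """
    rng = np.random.default_rng(_subseed(config.seed, "propensities"))
    base = config._vector("base_logits", 0.0)
    age_eff = config._vector("age_effects", 0.0)
    gen_eff = config._vector("gender_effects", 0.0)
    age = participants["age_bin"].to_numpy()[:, None]
    female = (participants["gender"] == "f").to_numpy()[:, None]
    logits = base[None, :] + age_eff[None, :] * age + gen_eff[None, :] * female
    if config.propensity_sd > 0:
        logits = logits + rng.normal(0.0, config.propensity_sd, logits.shape)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        probs,
        index=participants["participant_id"].to_numpy(),
        columns=[f"component_{k}" for k in range(config.n_components)],
    )


def _zipf_weights(m: int, s: float) -> np.ndarray:
    w = (np.arange(1, m + 1, dtype=float)) ** (-s)
    return w / w.sum()


def _draw_distinct(rng, words: list[np.ndarray], probs: list[np.ndarray],
                   comps: np.ndarray, n: int) -> tuple[list[str], list[int]]:
    """Draw n distinct words; comps[i] is the component of draw i.

    Repeats within the same cue page are rejection-resampled within the
    already-chosen component.
    """
    out: list[str] = []
    seen: set[str] = set()
    for k in comps[:n]:
        for _ in range(1000):
            w = words[k][rng.choice(len(words[k]), p=probs[k])]
            if w not in seen:
                break
        else:  # pragma: no cover - component exhausted, config validation prevents
            raise RuntimeError("could not draw a distinct word")
        seen.add(w)
        out.append(w)
    return out, list(comps[:n])


def generate_associations(
    lexicon: pd.DataFrame,
    participants: pd.DataFrame,
    config: GeneratorConfig,
    propensities: pd.DataFrame | None = None,
) -> AssociationDataset:
    """Simulate the mini-snowball task for every participant.

    Each participant contributes ``n_level1`` level-1 records (responses to
    the focal cue) and ``n_level2`` level-2 records per level-1 response.
    Level-1 responses are drawn from the participant's component propensity;
    level-2 responses come from the eliciting word's home component with
    probability ``1 - leakage`` and from a uniformly random other component
    otherwise.  Within any one cue page, responses are distinct.
    """
    if lexicon.empty:
        raise ValueError("lexicon is empty")
    if propensities is None:
        propensities = component_propensities(participants, config)
    rng = np.random.default_rng(_subseed(config.seed, "associations"))
    K = config.n_components
    by_comp = [
        lexicon.index[lexicon["component"] == k].to_numpy() for k in range(K)
    ]
    zipf = [_zipf_weights(len(w), config.zipf_exponent) for w in by_comp]
    home = lexicon["component"]

    rows = []
    prop = propensities.to_numpy()
    pid_order = participants["participant_id"].to_numpy()
    for i, pid in enumerate(pid_order):
        l1_comps = rng.choice(K, size=config.n_level1, p=prop[i])
        l1_words, _ = _draw_distinct(rng, by_comp, zipf, l1_comps, config.n_level1)
        for pos, w in enumerate(l1_words, start=1):
            rows.append((pid, 1, FOCAL_CUE, pd.NA, pos, w))
        for cue_pos, cue in enumerate(l1_words, start=1):
            hk = int(home[cue])
            comps = np.full(config.n_level2, hk)
            if config.leakage > 0:
                leak = rng.random(config.n_level2) < config.leakage
                if leak.any():
                    others = [k for k in range(K) if k != hk]
                    comps[leak] = rng.choice(others, size=int(leak.sum()))
            l2_words, _ = _draw_distinct(rng, by_comp, zipf, comps, config.n_level2)
            for pos, w in enumerate(l2_words, start=1):
                rows.append((pid, 2, cue, cue_pos, pos, w))

    records = pd.DataFrame(
        rows,
        columns=["participant_id", "level", "cue", "cue_position", "position", "response"],
    )
    demographics = participants[["participant_id", "age_bin", "gender"]].copy()
    return AssociationDataset(records=records, demographics=demographics)


# ---------------------------------------------------------------------------
# Survey


def generate_survey(
    participants: pd.DataFrame,
    propensities: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Seven 0-10 integer risk-propensity ratings per participant.

    rating_ij = round(clip(intercept_j + sum_k loading_k * propensity_ik
                           + Normal(0, noise_sd), 0, 10))
    """
    rng = np.random.default_rng(_subseed(config.seed, "survey"))
    loadings = config._vector("survey_loadings", 0.0)
    prop = propensities.loc[participants["participant_id"]].to_numpy()
    latent = prop @ loadings
    out = {"participant_id": participants["participant_id"].to_numpy()}
    for j, item in enumerate(SURVEY_ITEMS):
        x = config.survey_intercepts[j] + latent
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=len(latent))
        out[item] = np.clip(np.round(x), 0, 10).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Convenience


@dataclass
class SyntheticStudy:
    """Bundle of all generated artifacts for one simulated study."""

    config: GeneratorConfig
    lexicon: pd.DataFrame
    participants: pd.DataFrame
    propensities: pd.DataFrame
    dataset: AssociationDataset
    survey: pd.DataFrame

    @property
    def planted_labels(self) -> pd.Series:
        """Ground-truth component of every word in the lexicon."""
        return self.lexicon["component"]


def generate_study(config: GeneratorConfig | None = None, **kw) -> SyntheticStudy:
    """Run the full generator: lexicon, participants, associations, survey."""
    if config is None:
        config = default_config(**kw)
    elif kw:
        config = config.with_(**kw)
    lexicon = generate_lexicon(config)
    participants = generate_participants(config)
    propensities = component_propensities(participants, config)
    dataset = generate_associations(lexicon, participants, config, propensities)
    survey = generate_survey(participants, propensities, config)
    return SyntheticStudy(config, lexicon, participants, propensities, dataset, survey)


def _subseed(seed: int, stream: str) -> np.random.SeedSequence:
    """Independent, reproducible stream per generator stage."""
    tag = int.from_bytes(stream.encode(), "little") % (2**32)
    return np.random.SeedSequence(entropy=seed, spawn_key=(tag,))
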