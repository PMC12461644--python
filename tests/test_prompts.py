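"""Prompt templating, augmentation, and matching-rule behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medi2i.prompts import (
    KeywordSet, MedicalPrompt, MissingEssentialKeyword,
    augment_prompt, build_match_matrix, extract_keywords,
    load_normalization_table, match_prompts, render_prompt,
)

BRAIN_T2 = KeywordSet(organ="brain", modality="magnetic resonance imaging",
                      plane="axial", sequence="T2-weighted")

FULL = KeywordSet(
    organ="brain", modality="magnetic resonance imaging", plane="axial",
    sequence="T1-weighted", contrast="Gadolinium", preprocess="skull removal",
    manufacturer="Philips", manufacturer_model_name="Ingenia",
    magnetic_field_strength="3.0", scanning_sequence="GR",
    sequence_variant="SP", scan_options="FS", flip_angle="9",
    echo_time="4.6", repetition_time="9.8", inversion_time="900",
)


class TestExtractKeywords:
    def test_dicom_tags_normalized(self):
        ks = extract_keywords(
            {"Manufacturer": "Philips", "MagneticFieldStrength": 3.0,
             "Modality": "MR"},
            overrides={"Organ": "Brain", "Plane": "Axial"})
        assert ks.manufacturer == "Philips"
        assert ks.magnetic_field_strength == "3.0"
        assert ks.modality == "magnetic resonance imaging"
        assert ks.organ == "brain"          # lowercased
        assert ks.plane == "axial"

    def test_absent_tag_stays_absent(self):
        ks = extract_keywords({"Modality": "MR"},
                              overrides={"Organ": "brain", "Plane": "axial"})
        assert ks.echo_time is None

    def test_override_precedence(self):
        ks = extract_keywords({"BodyPartExamined": "head", "Modality": "MR"},
                              overrides={"Organ": "brain", "Plane": "axial"})
        assert ks.organ == "brain"

    def test_missing_essential_raises(self):
        with pytest.raises(MissingEssentialKeyword):
            extract_keywords({"Modality": "MR"}, overrides={"Plane": "axial"})

    def test_unknown_tags_ignored(self):
        ks = extract_keywords({"Modality": "MR", "PatientName": "X"},
                              overrides={"Organ": "brain", "Plane": "axial"})
        assert not hasattr(ks, "patient_name")


class TestRenderPrompt:
    def test_template_first_sentence_exact(self):
        prompt = render_prompt(BRAIN_T2)
        assert prompt.sentences[0][0] == \
            "A T2-weighted magnetic resonance imaging of the brain for the subject."
        assert prompt.sentences[0][1] is True

    def test_plane_sentence(self):
        prompt = render_prompt(BRAIN_T2)
        assert prompt.sentences[-1][0] == "The image is visualized in the axial plane."

    def test_no_contrast_no_contrast_sentence(self):
        prompt = render_prompt(BRAIN_T2)
        assert not any("contrast" in t for t in prompt.texts())

    def test_full_template_order_and_flags(self):
        prompt = render_prompt(FULL)
        texts = prompt.texts()
        assert texts[0].startswith("A T1-weighted magnetic resonance imaging")
        assert texts[1] == ("The subject undergoes the contrast-enhanced scan "
                            "with the Gadolinium agent.")
        assert texts[2] == "The scan is acquired on the Philips Ingenia 3.0 Tesla scanner."
        assert texts[3] == "The scanning sequences consist of GR."
        assert "an echo time of 4.6 ms" in texts[6]
        assert texts[7] == "The image preprocessing consists of skull removal."
        flags = dict(prompt.sentences)
        assert flags[texts[1]] and flags[texts[7]]      # contrast, preprocess essential
        assert not flags[texts[2]]                      # scanner optional

    def test_time_point_rendered_in_first_sentence(self):
        ks = KeywordSet(organ="breast", modality="magnetic resonance imaging",
                        plane="axial", sequence="DCE", sequence_frame_number="first")
        assert render_prompt(ks).sentences[0][0] == \
            "A first DCE magnetic resonance imaging of the breast for the subject."

    def test_injective_over_essential_tokens(self):
        seen = set()
        for seq in ("T1-weighted", "T2-weighted", None):
            for organ in ("brain", "breast"):
                for pre in ("skull removal", None):
                    ks = KeywordSet(organ=organ, plane="axial",
                                    modality="magnetic resonance imaging",
                                    sequence=seq, preprocess=pre)
                    seen.add(render_prompt(ks).text())
        assert len(seen) == 12


class TestAugmentPrompt:
    def test_essentials_always_survive(self):
        rng = np.random.default_rng(0)
        prompt = render_prompt(FULL)
        for _ in range(200):
            aug = augment_prompt(prompt, rng, drop_prob=0.9)
            assert prompt.essential_texts() <= set(aug.texts())

    def test_deterministic_given_seed(self):
        prompt = render_prompt(FULL)
        a = augment_prompt(prompt, np.random.default_rng(42), drop_prob=0.5)
        b = augment_prompt(prompt, np.random.default_rng(42), drop_prob=0.5)
        assert a.sentences == b.sentences

    def test_drop_prob_one_keeps_only_essentials(self):
        prompt = render_prompt(FULL)
        aug = augment_prompt(prompt, np.random.default_rng(1), drop_prob=1.0)
        assert set(aug.texts()) == prompt.essential_texts()

    def test_only_essential_prompt_unchanged_as_multiset(self):
        prompt = MedicalPrompt((("Sentence one.", True), ("Sentence two.", True)))
        aug = augment_prompt(prompt, np.random.default_rng(5), drop_prob=1.0)
        assert sorted(aug.texts()) == sorted(prompt.texts())

    def test_keep_first_pins_leading_sentence(self):
        prompt = render_prompt(FULL)
        for seed in range(20):
            aug = augment_prompt(prompt, np.random.default_rng(seed),
                                 drop_prob=0.3, keep_first=True)
            assert aug.sentences[0] == prompt.sentences[0]


class TestMatching:
    def test_reflexive(self):
        p = render_prompt(FULL)
        assert match_prompts(p, p)

    def test_augmented_always_matches_original(self):
        rng = np.random.default_rng(3)
        p = render_prompt(FULL)
        for _ in range(100):
            assert match_prompts(p, augment_prompt(p, rng, drop_prob=0.7))

    def test_dropping_optional_matches(self):
        p = render_prompt(FULL)
        optionals = [s for s in p.sentences if not s[1]]
        reduced = MedicalPrompt(tuple(s for s in p.sentences if s != optionals[0]))
        assert match_prompts(original=p, candidate=reduced)

    def test_extra_sentence_fails(self):
        p = render_prompt(FULL)
        extended = MedicalPrompt(p.sentences + (("An alien sentence.", False),))
        assert not match_prompts(original=p, candidate=extended)

    def test_asymmetry(self):
        p = render_prompt(FULL)
        optionals = [s for s in p.sentences if not s[1]]
        reduced = MedicalPrompt(tuple(s for s in p.sentences if s != optionals[0]))
        assert match_prompts(original=p, candidate=reduced)
        assert not match_prompts(original=reduced, candidate=p)

    def test_missing_essential_fails(self):
        p = render_prompt(FULL)
        # candidate missing the preprocessing (essential) sentence
        cand = MedicalPrompt(tuple(s for s in p.sentences
                                   if "preprocessing" not in s[0]))
        assert not match_prompts(original=p, candidate=cand)


def _oracle_match(original: MedicalPrompt, candidate: MedicalPrompt) -> bool:
    """Independent literal restatement of the sentence-subset rule."""
    orig = [t for t, _ in original.sentences]
    cand = [t for t, _ in candidate.sentences]
    ok_subset = all(any(c == o for o in orig) for c in cand)
    ok_essential = all(any(t == c for c in cand)
                       for t, e in original.sentences if e)
    return ok_subset and ok_essential


class TestMatchMatrix:
    def test_identical_prompts_all_ones(self):
        p = render_prompt(BRAIN_T2)
        m = build_match_matrix([p, p], [p, p])
        assert m.shape == (2, 2) and m.all()

    def test_one_prompt_two_images_row(self):
        p = render_prompt(FULL)
        other = render_prompt(BRAIN_T2)
        aug = augment_prompt(p, np.random.default_rng(0), drop_prob=1.0)
        m = build_match_matrix([p, p, other], [aug])
        assert m.tolist() == [[1, 1, 0]]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        base = [render_prompt(FULL), render_prompt(BRAIN_T2),
                render_prompt(KeywordSet(organ="abdomen", plane="coronal",
                                         modality="computed tomography"))]
        images = [base[int(rng.integers(3))] for _ in range(8)]
        texts = [augment_prompt(p, rng, drop_prob=0.5) for p in images]
        m = build_match_matrix(images, texts)
        for i, cand in enumerate(texts):
            for j, orig in enumerate(images):
                assert m[i, j] == _oracle_match(orig, cand)


class TestMatchingProperties:
    """Hypothesis-driven invariants of augmentation and matching."""

    @given(seed=st.integers(0, 2**31 - 1), drop=st.floats(0.0, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_augmented_prompt_always_matches_original(self, seed, drop):
        prompt = render_prompt(FULL)
        aug = augment_prompt(prompt, np.random.default_rng(seed), drop_prob=drop)
        assert match_prompts(original=prompt, candidate=aug)
        assert prompt.essential_texts() <= set(aug.texts())

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_match_matrix_row_of_own_augmentation_is_one(self, seed):
        rng = np.random.default_rng(seed)
        originals = [render_prompt(FULL), render_prompt(BRAIN_T2)]
        candidates = [augment_prompt(p, rng, drop_prob=0.5) for p in originals]
        m = build_match_matrix(originals, candidates)
        assert m[0, 0] == 1 and m[1, 1] == 1


def test_prompt_text_roundtrip(tmp_path):
    p = render_prompt(FULL)
    path = tmp_path / "prompt.txt"
    p.save(path)
    q = MedicalPrompt.load(path)
    assert q.sentences == p.sentences
    assert path.read_text().splitlines()[0].startswith("!")


def test_normalization_table_versioned():
    table = load_normalization_table()
    assert table["version"] >= 1
    assert table["ordinals"][0] == "first"
    assert table["units"]["echo_time"] == "ms"
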