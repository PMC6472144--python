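"""Lexicon parsing, tokenization, matching and indicator fractions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emosync.lexicon import (
    Lexicon,
    LexiconParseError,
    demo_lexicons,
    indicator_fraction,
    load_lexicon_json,
    load_liwc_dic,
    matches,
    save_lexicon_json,
    tokenize,
    union_lexicon,
    validate_percent_increase,
    write_liwc_dic,
)
from emosync._demo_lexicons import FILLER_WORDS


@pytest.mark.parametrize("text,expected", [
    ("Je suis à #Paris http://t.co/x @ami", ["je", "suis", "à", "paris"]),
    ("", []),
    ("Liberté, Égalité!", ["liberté", "égalité"]),
    ("RT @x: voilà 123 fois", ["rt", "voilà", "fois"]),
    ("aujourd'hui j’ai vu www.site.fr", ["aujourd'hui", "j'ai", "vu"]),
    ("#JeSuisParis  😢", ["jesuisparis"]),
])
def test_tokenize_rules(text, expected):
    assert tokenize(text) == expected


@pytest.mark.parametrize("entry,token,expected", [
    ("solidar*", "solidarité", True),
    ("ami", "amis", False),
    ("ami*", "ami", True),
    ("peur", "peur", True),
    ("peur", "apeuré", False),
])
def test_entry_matching(entry, token, expected):
    assert matches(entry, token) is expected


def test_indicator_fraction_examples():
    lex = Lexicon.from_entries("demo", ["chat", "chien*"])
    ten = ["chat", "chiens"] + ["autre"] * 8
    assert indicator_fraction(ten, lex) == pytest.approx(0.2)
    assert indicator_fraction([], lex) is None
    assert indicator_fraction(["chat", "chienne", "chat", "chien", "chiens"], lex) == 1.0


def test_token_matching_multiple_entries_counts_once():
    lex = Lexicon.from_entries("demo", ["soleil", "sol*"])
    assert indicator_fraction(["soleil", "lune"], lex) == pytest.approx(0.5)


@given(st.lists(st.sampled_from(FILLER_WORDS + ["peur", "horreur", "joie"]),
                min_size=1, max_size=40))
@settings(max_examples=100, deadline=None)
def test_fraction_bounds_and_case_insensitivity(words):
    lex = demo_lexicons()["negemo"]
    text = " ".join(words)
    f = lex.fraction(tokenize(text))
    assert 0.0 <= f <= 1.0
    assert f == lex.fraction(tokenize(text.upper()))


def test_adding_nonmatching_token_strictly_decreases_fraction(negemo):
    tokens = ["peur", "le", "jour"]
    base = negemo.fraction(tokens)
    assert base > 0
    assert negemo.fraction(tokens + ["table"]) < base


def test_lexicon_invariants():
    with pytest.raises(ValueError):
        Lexicon(name="x", literals=frozenset(), stems=())
    with pytest.raises(ValueError):
        Lexicon(name="x", literals=frozenset({"Ami"}), stems=())
    with pytest.raises(ValueError):
        Lexicon(name="x", literals=frozenset({"ami"}), stems=("ami",))


def test_dic_parse_and_roundtrip(tmp_path):
    p = tmp_path / "demo.dic"
    p.write_text("%\n1\tposemo\n%\nheureux\t1\ncontent*\t1\n", encoding="utf-8")
    lexs = load_liwc_dic(p)
    assert len(lexs) == 1
    (lex,) = lexs
    assert lex.name == "posemo"
    assert lex.literals == frozenset({"heureux"})
    assert lex.stems == ("content",)

    # write -> read is the identity on the full demo pack
    pack = list(demo_lexicons().values())
    out = tmp_path / "pack.dic"
    write_liwc_dic(pack, out)
    back = load_liwc_dic(out)
    assert {l.name: set(l.entries) for l in back} == {l.name: set(l.entries) for l in pack}


def test_json_roundtrip(tmp_path):
    pack = list(demo_lexicons().values())
    out = tmp_path / "pack.json"
    save_lexicon_json(pack, out)
    back = load_lexicon_json(out)
    assert {l.name: set(l.entries) for l in back} == {l.name: set(l.entries) for l in pack}


@pytest.mark.parametrize("content,msg", [
    ("1 posemo\nheureux 1\n", "header"),                      # missing % delimiters
    ("%\n1\tposemo\n%\nheureux\t99\n", "unknown category"),   # bad id
    ("%\n1\tposemo\n2\tnegemo\n%\nheureux\t1\n", "no words"), # empty category
    ("%\nposemo\n%\nheureux\t1\n", "malformed header"),
])
def test_dic_parse_errors(tmp_path, content, msg):
    p = tmp_path / "bad.dic"
    p.write_text(content, encoding="utf-8")
    with pytest.raises(LexiconParseError, match=msg):
        load_liwc_dic(p)


def test_validate_percent_increase():
    lex = Lexicon.from_entries("posemo", ["heureux", "joie"])
    pos = ["heureux joie le la", "joie le la tard"]     # means 0.5, 0.25
    ctrl = ["heureux le la tard", "le la tard encore"]  # means 0.25, 0.0
    # (0.375 / 0.125 - 1) * 100 = +200%
    assert validate_percent_increase(pos, ctrl, lex) == pytest.approx(200.0)
    assert validate_percent_increase(pos, pos, lex) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="percent increase undefined"):
        validate_percent_increase(pos, ["le la", "tard encore"], lex)


def test_demo_filler_matches_no_category(lexicons):
    for word in FILLER_WORDS:
        for name, lex in lexicons.items():
            assert not lex.matches_token(word), (word, name)


def test_union_lexicon(lexicons):
    affect = union_lexicon("affect", [lexicons["posemo"], lexicons["negemo"]])
    assert affect.matches_token("joie") and affect.matches_token("peur")
    # a token in both categories counts once in the union fraction
    assert affect.fraction(["joie", "peur"]) == 1.0
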