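"""Synthetic demo lexicon pack.

A small, hand-written set of French-flavoured word categories used by the
synthetic generators and the test fixtures.  It mimics the *shape* of a
LIWC-style dictionary (literal entries plus ``*`` stem entries, overlapping
categories such as sadness ⊂ negative affect) but is in no way a
reproduction of any licensed dictionary: real analyses must supply their own
lexicon files.

``FILLER_WORDS`` is the generator's background vocabulary; it is guaranteed
(and tested) to match no category, so emission probabilities translate
directly into indicator fractions.
"""

# category -> entries; trailing "*" marks a stem (prefix) entry
DEMO_CATEGORY_WORDS: dict[str, list[str]] = {
    "posemo": [
        "heureux", "heureuse", "joie", "joyeu*", "content*", "sourire",
        "espoir", "amour", "magnifique", "bonheur", "formidable", "merveill*",
    ],
    "negemo": [
        "triste*", "peur", "horreur", "terrible", "affreu*", "colère",
        "haine", "douleur", "pleur*", "cauchemar", "angoiss*", "rage",
    ],
    "sadness": [
        "triste*", "chagrin", "deuil", "larme*", "pleur*", "mélancolie",
    ],
    "anxiety": [
        "peur", "angoiss*", "inquiet*", "anxieu*", "panique", "effray*",
    ],
    "anger": [
        "colère", "rage", "furieu*", "haine", "énervé*", "indign*",
    ],
    "social": [
        "ami*", "famille", "ensemble", "frère*", "soeur*", "voisin*",
        "gens", "équipe", "parl*", "discut*", "rencontr*", "célébr*",
    ],
    "prosocial": [
        "solidarité", "solidaire*", "entraide", "aider", "bénévol*",
        "soutien*", "secour*", "ong", "généreu*", "charité",
    ],
    "shared_values": [
        "liberté*", "égalité*", "fraternité*", "république", "valeurs",
        "devise", "citoyen*", "nation*",
    ],
    "i": [
        "je", "j'*", "me", "moi", "mon", "ma", "mes",
    ],
    "attack_ref": [
        "attentat*", "attaque*", "terreur", "terroris*", "fusillade",
        "explosion",
    ],
}

# Background vocabulary: must not match any entry above (unit-tested).
FILLER_WORDS: list[str] = [
    "le", "la", "les", "un", "une", "des", "et", "ou", "dans", "sur",
    "pour", "avec", "sans", "que", "qui", "est", "sont", "être", "avoir",
    "faire", "aller", "voir", "jour", "nuit", "temps", "ville", "rue",
    "maison", "travail", "école", "musique", "film", "livre", "café",
    "matin", "soir", "semaine", "année", "chose", "table", "train",
    "fenêtre", "jardin", "pain", "eau", "ciel", "pluie", "soleil",
    "chemin", "porte", "page", "photo", "match", "vélo", "bus", "gare",
    "pont", "place", "marché", "montagne", "plage", "fleuve", "forêt",
    "hiver", "été", "automne", "printemps", "lundi", "mardi", "chanson",
]
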