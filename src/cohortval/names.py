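"""Synthetic Brazilian-style name pools for identity generation.

These small pools exist only so that synthetic identities look like the
free-text fields a real registry would hold (given name + one or two
surnames, diacritics included so that normalization is exercised).  They
are entirely synthetic and imply nothing about any real person.
"""

GIVEN_NAMES = [
    "MARIA", "JOSÉ", "ANA", "JOÃO", "ANTÔNIO", "FRANCISCA", "CARLOS",
    "PAULO", "ADRIANA", "PEDRO", "LUCAS", "LUIZA", "MARCOS", "JULIANA",
    "RAFAEL", "FERNANDA", "GABRIEL", "PATRÍCIA", "DANIEL", "ALINE",
    "MARCELO", "CAMILA", "BRUNO", "AMANDA", "EDUARDO", "BRUNA", "FELIPE",
    "JÉSSICA", "RODRIGO", "LETÍCIA", "GUSTAVO", "VANESSA", "RICARDO",
    "MARIANA", "TIAGO", "GABRIELA", "SÉRGIO", "ISABELA", "VINÍCIUS",
    "LARISSA", "LEONARDO", "BEATRIZ", "ANDRÉ", "NATÁLIA", "FÁBIO",
    "CAROLINA", "DIEGO", "RENATA", "MATEUS", "TATIANE",
]

FEMALE_GIVEN_NAMES = [
    "MARIA", "ANA", "FRANCISCA", "ADRIANA", "LUIZA", "JULIANA",
    "FERNANDA", "PATRÍCIA", "ALINE", "CAMILA", "AMANDA", "BRUNA",
    "JÉSSICA", "LETÍCIA", "VANESSA", "MARIANA", "GABRIELA", "ISABELA",
    "LARISSA", "BEATRIZ", "NATÁLIA", "CAROLINA", "RENATA", "TATIANE",
    "APARECIDA", "TEREZINHA", "SANDRA", "MÁRCIA", "CLÁUDIA", "REGINA",
]

SURNAMES = [
    "SILVA", "SANTOS", "OLIVEIRA", "SOUZA", "RODRIGUES", "FERREIRA",
    "ALVES", "PEREIRA", "LIMA", "GOMES", "COSTA", "RIBEIRO", "MARTINS",
    "CARVALHO", "ALMEIDA", "LOPES", "SOARES", "FERNANDES", "VIEIRA",
    "BARBOSA", "ROCHA", "DIAS", "NASCIMENTO", "ANDRADE", "MOREIRA",
    "NUNES", "MARQUES", "MACHADO", "MENDES", "FREITAS", "CARDOSO",
    "RAMOS", "GONÇALVES", "SANTANA", "TEIXEIRA", "ARAÚJO", "PINTO",
    "CORREIA", "MONTEIRO", "MOURA",
]

SURNAME_CONNECTORS = ["", "DA", "DE", "DOS"]
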