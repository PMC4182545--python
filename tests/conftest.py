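import datetime

import pytest

from cohortscreen import (ClinicalDocument, Corpus, DiagnosisAssignment,
                          PatientRecord)


def d(iso: str) -> datetime.date:
    return datetime.date.fromisoformat(iso)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Three patients: a female CAH-coded case, a male hypospadias-coded
    patient, and a male whose only code is the female-restricted 255.2."""
    corpus = Corpus(
        patients=[
            PatientRecord("p1", "F", d("2008-03-10")),
            PatientRecord("p2", "M", d("2009-07-01")),
            PatientRecord("p3", "M", d("2010-01-20")),
        ],
        diagnoses=[
            DiagnosisAssignment("p1", "255.2", d("2008-04-01")),
            DiagnosisAssignment("p2", "752.61", d("2009-08-15")),
            DiagnosisAssignment("p3", "255.2", d("2010-02-01")),
        ],
        documents=[
            ClinicalDocument("n1", "p1", "progress note", d("2008-05-01"),
                             "Karyotype returned 46 XX; congenital adrenal "
                             "hyperplasia suspected."),
            ClinicalDocument("n2", "p2", "operative note", d("2009-09-01"),
                             "Severe hypospadias repair with chordee release."),
            ClinicalDocument("n3", "p3", "progress note", d("2010-03-01"),
                             "Routine visit, no concerns."),
        ],
    )
    corpus.validate()
    corpus.sort()
    return corpus


@pytest.fixture
def corpus_files(tiny_corpus, tmp_path):
    from cohortscreen import write_corpus
    return write_corpus(tiny_corpus, tmp_path)
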