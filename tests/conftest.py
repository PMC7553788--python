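import datetime as dt

import pytest

from infodem import Corpus, Document


def make_doc(i, source="news", title="", body="", score=0, comments=0,
             author="", day=0):
    return Document(id=f"d{i:04d}",
                    timestamp=dt.date(2020, 2, 7) + dt.timedelta(days=day),
                    source=source, title=title, body=body, score=score,
                    comment_count=comments, author_id=author)


@pytest.fixture
def toy_news_corpus():
    titles = ["covid-19 surges", "election news", "SARS-CoV-2 study"]
    return Corpus([make_doc(i, title=t) for i, t in enumerate(titles)])
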