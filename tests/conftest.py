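import pytest

import rimskit as rk


@pytest.fixture
def repo(tmp_path):
    r = rk.Repository.init(tmp_path / "repo")
    yield r
    r.close()


@pytest.fixture
def admin(repo):
    """Bootstrap Superadministrator account."""
    return repo.find_user("admin")


@pytest.fixture
def users(repo, admin):
    """One user per role: superadmin (bootstrap), administrator, moderator,
    plain user."""
    return {
        "super": admin,
        "administrator": rk.create_user(repo, admin.id, "alice",
                                        rk.Role.ADMINISTRATOR),
        "moderator": rk.create_user(repo, admin.id, "bob", rk.Role.MODERATOR),
        "user": rk.create_user(repo, admin.id, "carol", rk.Role.USER),
    }


@pytest.fixture
def project(repo, users):
    """A root project owned by the moderator."""
    return rk.create_project(repo, "Study A", "a study",
                             owner_id=users["moderator"].id)


def make_template(repo, owner_id, name="T", n_char=2, n_ann=3, **def_kwargs):
    tpl = rk.create_template(repo, name, ["kw"], "test schema", owner_id)
    for i in range(n_char):
        tpl = rk.add_def(repo, tpl.id, "characteristic",
                         rk.FieldDef(name=f"char_{i}", **def_kwargs), owner_id)
    for i in range(n_ann):
        tpl = rk.add_def(repo, tpl.id, "annotation",
                         rk.FieldDef(name=f"ann_{i}", **def_kwargs), owner_id)
    return tpl
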