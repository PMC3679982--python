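"""Template engine: defs, locking, linking, validation, compliance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rimskit as rk

from conftest import make_template


class TestCreateTemplate:
    def test_created_unlocked_with_empty_defs(self, repo, admin):
        t = rk.create_template(
            repo, "Breast Cancer Transcriptome Template",
            ["Transcriptome", "Breast", "Cancer", "Clinical", "Data"],
            "Template for describing microarray of breast cancer samples",
            admin.id)
        assert t.locked is False
        assert t.characteristic_defs == () and t.annotation_defs == ()

    def test_duplicate_name_rejected(self, repo, admin):
        rk.create_template(repo, "T", [], "", admin.id)
        with pytest.raises(rk.DuplicateNameError):
            rk.create_template(repo, "T", [], "", admin.id)

    def test_plain_user_cannot_create(self, repo, users):
        with pytest.raises(rk.PermissionDeniedError):
            rk.create_template(repo, "T", [], "", users["user"].id)


class TestAddDef:
    def test_order_preserved(self, repo, admin):
        t = rk.create_template(repo, "T", [], "", admin.id)
        for name in ("Organism", "Platform Vendor", "Platform Type"):
            t = rk.add_def(repo, t.id, "characteristic",
                           rk.FieldDef(name=name), admin.id)
        assert [d.name for d in t.characteristic_defs] == [
            "Organism", "Platform Vendor", "Platform Type"]

    def test_experimental_question_flag_stored(self, repo, admin):
        t = rk.create_template(repo, "T", [], "", admin.id)
        for name in ("e.dmfs", "t.dmfs"):
            t = rk.add_def(repo, t.id, "annotation",
                           rk.FieldDef(name=name, experimental_question=True),
                           admin.id)
        assert all(d.experimental_question for d in t.annotation_defs)

    def test_locked_template_rejects_mutation(self, repo, admin):
        t = make_template(repo, admin.id)
        rk.create_project(repo, "p", owner_id=admin.id, template_id=t.id)
        with pytest.raises(rk.TemplateLockedError):
            rk.add_def(repo, t.id, "annotation", rk.FieldDef(name="late"),
                       admin.id)

    def test_default_and_value_list_mutually_exclusive(self, repo, admin):
        t = rk.create_template(repo, "T", [], "", admin.id)
        with pytest.raises(rk.ValidationError):
            rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="bad", default_value="x",
                                   value_list=("a", "b")), admin.id)

    def test_duplicate_def_name_rejected(self, repo, admin):
        t = rk.create_template(repo, "T", [], "", admin.id)
        t = rk.add_def(repo, t.id, "annotation", rk.FieldDef(name="a"), admin.id)
        with pytest.raises(rk.DuplicateNameError):
            rk.add_def(repo, t.id, "annotation", rk.FieldDef(name="a"), admin.id)

    def test_non_owner_moderator_cannot_edit_template(self, repo, users):
        t = rk.create_template(repo, "T", [], "", users["moderator"].id)
        other = rk.create_user(repo, users["super"].id, "eve",
                               rk.Role.MODERATOR)
        with pytest.raises(rk.PermissionDeniedError):
            rk.add_def(repo, t.id, "annotation", rk.FieldDef(name="a"), other.id)


class TestLinkTemplate:
    def test_counts_equal_def_list_lengths_and_lock(self, repo, admin):
        t = make_template(repo, admin.id, n_char=5, n_ann=6)
        p = rk.create_project(repo, "p", owner_id=admin.id)
        report = rk.link_template(repo, p.id, t.id, admin.id)
        assert (report.characteristics_added, report.annotations_added) == (5, 6)
        assert repo.get_template(t.id).locked is True

    def test_empty_template_links_and_locks(self, repo, admin):
        t = rk.create_template(repo, "empty", [], "", admin.id)
        p = rk.create_project(repo, "p", owner_id=admin.id)
        report = rk.link_template(repo, p.id, t.id, admin.id)
        assert (report.characteristics_added, report.annotations_added) == (0, 0)
        assert repo.get_template(t.id).locked is True

    def test_second_link_rejected(self, repo, admin):
        t1 = make_template(repo, admin.id, name="T1")
        t2 = make_template(repo, admin.id, name="T2")
        p = rk.create_project(repo, "p", owner_id=admin.id, template_id=t1.id)
        with pytest.raises(rk.ValidationError):
            rk.link_template(repo, p.id, t2.id, admin.id)

    def test_existing_files_receive_effective_defaults(self, repo, admin, tmp_path):
        p = rk.create_project(repo, "p", owner_id=admin.id)
        f = tmp_path / "s1.dat"
        f.write_bytes(b"xyz")
        rk.import_files(repo, p.id, f, admin.id)
        t = rk.create_template(repo, "T", [], "", admin.id)
        t = rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="organism",
                                   value_list=("human", "mouse")), admin.id)
        t = rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="batch", default_value="b1"), admin.id)
        t = rk.add_def(repo, t.id, "annotation", rk.FieldDef(name="note"),
                       admin.id)
        rk.link_template(repo, p.id, t.id, admin.id)
        (mf,) = repo.files_of(p.id)
        assert mf.annotation_values == {
            "organism": "human", "batch": "b1", "note": ""}

    def test_lock_never_reverts(self, repo, admin):
        """Lock monotonicity over an operation sequence."""
        t = make_template(repo, admin.id)
        p = rk.create_project(repo, "p", owner_id=admin.id, template_id=t.id)
        assert repo.get_template(t.id).locked
        rk.copy_project(repo, p.id, None, admin.id)
        rk.edit_project(repo, p.id, {"description": "x"}, admin.id)
        assert repo.get_template(t.id).locked


class TestCopyProjectAsTemplate:
    def test_templated_source_reproduces_defs_unlocked(self, repo, admin):
        src_tpl = make_template(repo, admin.id, n_char=5, n_ann=6)
        p = rk.create_project(repo, "p", owner_id=admin.id,
                              template_id=src_tpl.id)
        t = rk.copy_project_as_template(repo, p.id, "derived", admin.id)
        source = repo.get_template(src_tpl.id)
        assert t.locked is False
        assert t.characteristic_defs == source.characteristic_defs
        assert t.annotation_defs == source.annotation_defs

    def test_template_less_source_uses_observed_keys(self, repo, admin, tmp_path):
        p = rk.create_project(repo, "p", owner_id=admin.id)
        for i, keys in enumerate([{"a": "1"}, {"b": "2"}]):
            f = tmp_path / f"f{i}.dat"
            f.write_bytes(b"z")
            (mf,) = rk.import_files(repo, p.id, f, admin.id)
            repo.set_file_annotations(mf.id, keys)
        t = rk.copy_project_as_template(repo, p.id, "derived", admin.id)
        assert [d.name for d in t.annotation_defs] == ["a", "b"]
        assert all(d.default_value is None and d.value_list is None
                   for d in t.annotation_defs)

    def test_name_collision_rejected(self, repo, admin):
        tpl = make_template(repo, admin.id, name="taken")
        p = rk.create_project(repo, "p", owner_id=admin.id, template_id=tpl.id)
        with pytest.raises(rk.DuplicateNameError):
            rk.copy_project_as_template(repo, p.id, "taken", admin.id)


class TestValidateValue:
    @pytest.mark.parametrize("d,value,ok", [
        (rk.FieldDef(name="p", value_list=("GPL96", "GPL570")), "GPL96", True),
        (rk.FieldDef(name="p", value_list=("GPL96", "GPL570")), "GPL999", False),
        (rk.FieldDef(name="m", mandatory=True), "", False),
        (rk.FieldDef(name="m", mandatory=True), "x", True),
        (rk.FieldDef(name="f"), "", True),
        (rk.FieldDef(name="f"), "anything", True),
        (rk.FieldDef(name="vm", value_list=("a",), mandatory=True), "", False),
    ])
    def test_membership_and_mandatory_rules(self, d, value, ok):
        assert (rk.validate_value(d, value) is None) is ok

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(value=st.text(max_size=8),
           values=st.lists(st.text(min_size=1, max_size=4), min_size=1,
                           max_size=4, unique=True),
           mandatory=st.booleans())
    def test_pure_and_consistent(self, value, values, mandatory):
        d = rk.FieldDef(name="x", value_list=tuple(values), mandatory=mandatory)
        first = rk.validate_value(d, value)
        assert first == rk.validate_value(d, value)  # pure
        expected_ok = (value == "" and not mandatory) or value in values
        assert (first is None) == expected_ok


class TestMiCompliance:
    def _setup(self, repo, admin, tmp_path):
        t = rk.create_template(repo, "T", [], "", admin.id)
        t = rk.add_def(repo, t.id, "characteristic",
                       rk.FieldDef(name="Organism", mandatory=True), admin.id)
        t = rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="age", mandatory=True), admin.id)
        t = rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="er", value_list=("0", "1")), admin.id)
        p = rk.create_project(repo, "p", owner_id=admin.id)
        for i in range(3):
            f = tmp_path / f"s{i}.dat"
            f.write_bytes(b"d")
            rk.import_files(repo, p.id, f, admin.id)
        rk.link_template(repo, p.id, t.id, admin.id)
        rk.set_characteristic(repo, p.id, "Organism", "Homo sapiens", admin.id)
        rk.set_default_annotations(repo, p.id, {"age": "50", "er": "1"},
                                   admin.id)
        return p, t

    def test_fully_populated_project_is_compliant(self, repo, admin, tmp_path):
        p, t = self._setup(repo, admin, tmp_path)
        violations = rk.check_mi_compliance(repo, p.id)
        assert violations == []
        # brute-force oracle: re-validate every cell independently
        tpl = repo.get_template(t.id)
        cells = [(mf, d) for mf in repo.files_of(p.id)
                 for d in tpl.annotation_defs]
        assert all(
            rk.validate_value(d, mf.annotation_values.get(d.name, "")) is None
            for mf, d in cells)

    def test_one_blanked_mandatory_annotation_is_one_violation(
            self, repo, admin, tmp_path):
        p, _ = self._setup(repo, admin, tmp_path)
        mf = repo.files_of(p.id)[0]
        values = dict(mf.annotation_values)
        values["age"] = ""
        repo.set_file_annotations(mf.id, values)
        violations = rk.check_mi_compliance(repo, p.id)
        assert len(violations) == 1
        assert violations[0].object_name == mf.filename
        assert violations[0].field_name == "age"

    def test_missing_mandatory_characteristic_reported(self, repo, admin,
                                                       tmp_path):
        p, _ = self._setup(repo, admin, tmp_path)
        repo.db.execute(
            "UPDATE projects SET characteristics = '{}' WHERE id = ?", (p.id,))
        violations = rk.check_mi_compliance(repo, p.id)
        assert [v.scope for v in violations] == ["project"]

    def test_template_less_project_is_an_error(self, repo, admin):
        p = rk.create_project(repo, "p", owner_id=admin.id)
        with pytest.raises(rk.NotFoundError):
            rk.check_mi_compliance(repo, p.id)


class TestSerialization:
    def test_yaml_round_trip_preserves_defs(self, repo, admin):
        t = rk.create_template(repo, "RT", ["k1", "k2"], "desc", admin.id)
        t = rk.add_def(repo, t.id, "characteristic",
                       rk.FieldDef(name="Organism", default_value="Homo sapiens"),
                       admin.id)
        t = rk.add_def(repo, t.id, "annotation",
                       rk.FieldDef(name="e.dmfs", experimental_question=True,
                                   value_list=("0", "1"), mandatory=True),
                       admin.id)
        text = rk.dump_template(t)
        t2 = rk.load_template(repo, text.replace("RT", "RT2"), admin.id)
        assert t2.characteristic_defs == t.characteristic_defs
        assert t2.annotation_defs == t.annotation_defs
        assert t2.keywords == t.keywords
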