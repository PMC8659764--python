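"""Block-codec unit and property tests: token grammar, geometry, round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepglove import codec
from sleepglove.codec import (
    PPG_MAX,
    SampleStream,
    Token,
    TokenKind,
    decode_file,
    encode_delta,
    encode_recording,
    encode_spo2,
    xor_checksum,
)


class TestXorChecksum:
    def test_empty_is_zero(self):
        assert xor_checksum(b"") == 0

    def test_worked_fold(self):
        assert xor_checksum(bytes([0x01, 0x02, 0x03])) == 0x00

    @given(st.binary(max_size=64))
    @settings(deadline=None)
    def test_self_inverse(self, b):
        assert xor_checksum(b + b) == 0


class TestSpo2Encoding:
    @pytest.mark.parametrize("percent, code", [
        (100, 63),   # top of the representable range
        (37, 0),     # offset boundary = artifact sentinel
        (97, 60),
        (20, 0),     # below offset clamps to the artifact code
        (110, 63),   # unrepresentable high reading clamps
    ])
    def test_offset_code(self, percent, code):
        tok = encode_spo2(percent)
        assert tok.kind is TokenKind.SPO2 and tok.value == code

    def test_decode_inverts_in_range(self):
        for pct in range(38, 101):
            assert codec.decode_spo2(encode_spo2(pct).value) == pct


class TestEncodeDelta:
    def test_small_delta_is_dd(self):
        toks = encode_delta(1000, 1005)
        assert [t.kind for t in toks] == [TokenKind.DD] and toks[0].value == 5

    def test_zero_delta(self):
        assert encode_delta(4242, 4242)[0].value == 0

    def test_scale_factoring_picks_smallest_exact_scale(self):
        toks = encode_delta(0, 512)
        assert [t.kind for t in toks] == [TokenKind.SF, TokenKind.DD]
        scale = codec.SCALES[toks[0].value]
        assert scale == 8 and toks[1].value == 64 and scale * toks[1].value == 512

    def test_unfactorable_delta_falls_back_to_av(self):
        # 127*256 = 32512 is the largest factorable magnitude; odd deltas
        # beyond 127 with no exact 8-bit quotient must resync as AV
        toks = encode_delta(0, 32513)
        assert [t.kind for t in toks] == [TokenKind.AV]
        assert toks[0].value == 32513

    @given(st.integers(0, PPG_MAX), st.integers(0, PPG_MAX))
    @settings(deadline=None, max_examples=300)
    def test_lossless_contract(self, prev, cur):
        toks = encode_delta(prev, cur)
        if toks[0].kind is TokenKind.DD:
            assert prev + toks[0].value == cur
        elif toks[0].kind is TokenKind.SF:
            assert prev + codec.SCALES[toks[0].value] * toks[1].value == cur
        else:
            assert toks[0].value == cur

    def test_out_of_range_value_rejected(self):
        with pytest.raises(codec.CodecError):
            encode_delta(0, PPG_MAX + 1)


class TestTokenInvariants:
    @pytest.mark.parametrize("kind, bad", [
        (TokenKind.DD, 200), (TokenKind.AV, -1), (TokenKind.SF, 8),
        (TokenKind.SPO2, 64), (TokenKind.MOVE, 1 << 16),
    ])
    def test_payload_ranges_enforced(self, kind, bad):
        with pytest.raises(codec.CodecError):
            Token(kind, bad)


def _random_stream(rng, n=None):
    n = n or int(rng.integers(10, 400))
    # mostly 8-bit deltas with occasional large jumps (SF / AV paths)
    deltas = rng.integers(-100, 101, n)
    jumps = rng.random(n) < 0.02
    deltas[jumps] = rng.integers(-5000, 5001, jumps.sum())
    ppg = np.clip(np.cumsum(deltas) + PPG_MAX // 2, 0, PPG_MAX)
    spo2 = rng.integers(88, 100, (n - 1) // 100 + 1)
    moves = rng.integers(0, 200, (n - 1) // 6000 + 1)
    return SampleStream(ppg, spo2, moves)


class TestRoundTrip:
    def test_constant_second_is_av_then_dd_zeros(self):
        stream = SampleStream(np.full(100, 1000), np.array([97]), np.array([0]))
        frames = encode_recording(stream)
        assert len(frames) == 1
        block = codec.EncodedBlock.from_bytes(frames[0].block_bytes)
        events = codec._decode_block_events(block)
        ppg_events = [e for e in events if e[0] in ("AV", "DD", "SF", "GB")]
        assert ppg_events[0] == ("AV", 1000, 0)
        assert all(e == ("DD", 0, 0) for e in ppg_events[1:])
        assert len(ppg_events) == 100

    def test_many_randomized_streams_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            stream = _random_stream(rng)
            assert decode_file(encode_recording(stream)).equals(stream)

    def test_block_geometry(self):
        rng = np.random.default_rng(1)
        frames = encode_recording(_random_stream(rng, 20000))
        for frame in frames:
            assert len(frame.block_bytes) == codec.BLOCK_PADDED_BYTES
            block = codec.EncodedBlock.from_bytes(frame.block_bytes)
            assert len(block.rows) == codec.N_ROWS
            assert len(block.rows[0].payload) == codec.ROW1_PAYLOAD_BYTES
            assert all(len(r.payload) == codec.ROW_PAYLOAD_BYTES
                       for r in block.rows[1:])
            # raw geometry: 25 rows x 157 B before flash padding
            raw = frame.block_bytes[: codec.BLOCK_RAW_BYTES]
            assert len(raw) == 25 * 157

    def test_blocks_start_with_av(self):
        rng = np.random.default_rng(2)
        frames = encode_recording(_random_stream(rng, 30000))
        assert len(frames) > 2
        for frame in frames:
            block = codec.EncodedBlock.from_bytes(frame.block_bytes)
            events = codec._decode_block_events(block)
            assert events[0][0] == "AV"

    def test_decode_invariant_under_frame_permutation(self):
        rng = np.random.default_rng(3)
        stream = _random_stream(rng, 25000)
        frames = encode_recording(stream)
        perm = list(rng.permutation(len(frames)))
        assert decode_file([frames[i] for i in perm]).equals(stream)

    def test_empty_stream_rejected(self):
        with pytest.raises(codec.CodecError):
            encode_recording(SampleStream(np.array([], dtype=int),
                                          np.array([]), np.array([])))


class TestCorruption:
    def test_checksum_rejects_single_byte_flip(self):
        rng = np.random.default_rng(4)
        stream = _random_stream(rng, 25000)
        frames = encode_recording(stream)
        for pos in (0, 100, 2000, codec.BLOCK_RAW_BYTES - 1):
            bad = bytearray(frames[2].block_bytes)
            bad[pos] ^= 0x55
            tampered = codec.TransportFrame(frames[2].device_id,
                                            frames[2].checksum, bytes(bad))
            assert not tampered.verify()

    def test_corrupt_block_becomes_gap_rest_intact(self):
        rng = np.random.default_rng(5)
        stream = _random_stream(rng, 25000)
        frames = list(encode_recording(stream))
        bad = bytearray(frames[2].block_bytes)
        bad[500] ^= 0xFF
        frames[2] = codec.TransportFrame(frames[2].device_id,
                                         frames[2].checksum, bytes(bad))
        out = decode_file(frames)
        assert len(out.gaps) == 1
        a, b = out.gaps[0]
        assert not out.ppg_valid[a:b].any()
        mask = np.ones(len(stream.ppg), dtype=bool)
        mask[a:b] = False
        assert np.array_equal(out.ppg[mask], stream.ppg[mask])

    def test_duplicate_counter_keeps_first(self):
        rng = np.random.default_rng(6)
        stream = _random_stream(rng, 10000)
        frames = list(encode_recording(stream))
        assert decode_file(frames + [frames[1]]).equals(stream)


class TestArtifacts:
    def test_gb_sample_invalid_and_resynced(self):
        rng = np.random.default_rng(7)
        stream = _random_stream(rng, 5000)
        stream.ppg_valid[1234] = False
        out = decode_file(encode_recording(stream))
        assert not out.ppg_valid[1234]
        assert (1234, 1235) in out.gaps
        mask = out.ppg_valid
        assert mask.sum() == len(stream.ppg) - 1
        assert np.array_equal(out.ppg[mask], stream.ppg[mask])


class TestFileFormat:
    def test_bin_file_round_trip_with_shuffled_blocks(self, tmp_path):
        rng = np.random.default_rng(8)
        stream = _random_stream(rng, 30000)
        frames = encode_recording(stream, device_id="DEV-42")
        path = tmp_path / "rec.bin"
        codec.write_bin(frames, path, rng=np.random.default_rng(9))
        back = codec.read_bin(path)
        assert all(f.device_id == "DEV-42" for f in back)
        assert decode_file(back).equals(stream)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        stream = _random_stream(rng, 12000)
        path = tmp_path / "rec.csv"
        codec.stream_to_csv(stream, path)
        back = codec.stream_from_csv(path)
        assert back.equals(stream)


class TestCompressionBound:
    def test_delta_friendly_stream_close_to_nine_bits_per_sample(self):
        rng = np.random.default_rng(11)
        n = 100_000
        ppg = np.clip(np.cumsum(rng.integers(-100, 101, n)) + PPG_MAX // 2,
                      0, PPG_MAX)
        stream = SampleStream(ppg, rng.integers(90, 100, n // 100),
                              np.zeros((n - 1) // 6000 + 1, dtype=int))
        frames = encode_recording(stream)
        total_bits = 8 * codec.BLOCK_PADDED_BYTES * len(frames)
        # 9 data bits/sample plus row, counter and flash-padding overhead
        assert total_bits / n < 9 * 1.15
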