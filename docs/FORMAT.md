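# The `.bin` recording format

A recording is a concatenation of transport frames, one per 4 KB flash
block. Frames need not be stored chronologically — the decoder orders
blocks by their sample counters.

## Transport frame

| field        | size    | content                                        |
|--------------|---------|------------------------------------------------|
| header length| 4 B LSB-first | byte length of the JSON header           |
| header       | variable| `{"device_id": "...", "checksum": N}`          |
| block        | 4096 B  | encoded block, zero-padded from 3925 B         |

The checksum is the XOR fold of all 4096 block bytes, reduced to 8 bits.
A frame whose checksum does not verify is dropped and its sample range
becomes a gap.

The recommended filename is `<userID>_<ISO8601 start time>.bin`.

## Block layout — 25 rows × 157 bytes

```
row 1    : [4 B sample counter, LSB-first][2 B useful bits, LSB-first][151 B payload]
rows 2-25: [2 B useful bits, LSB-first][155 B payload]
```

25 × 157 = 3925 bytes, padded with zeros to the 4096-byte flash block.
The sample counter is the number of PPG samples produced by the drivers
before the first PPG sample of this block (PPG runs at 100 Hz, so the
counter fixes the block's position on the time axis). `useful bits`
counts the informative bits of that row's payload; bits beyond it carry
no information. A token is never split across rows: when the next token
does not fit, the row is closed and encoding continues on the next row.

## Token grammar

Payload bits are packed most-significant-bit first. Multi-bit integer
payloads are unsigned big-endian within the bit stream except DD, which
is an 8-bit two's-complement signed value.

| prefix  | token | payload | meaning |
|---------|-------|---------|---------|
| `0`     | DD    | 8 b signed | PPG delta vs the previous sample |
| `10`    | GB    | none    | garbage: artifact sample, value dropped |
| `110`   | AV    | 18 b    | absolute PPG value |
| `1110`  | SF    | 3 b + 8 b | scale code, then the bare signed quotient |
| `11110` | SpO2  | 6 b     | saturation percent minus 37, 0 = artifact |
| `111110`| Move  | 16 b    | movement count for the elapsed minute |

* The first data token of every block is AV, so each block decodes
  independently of the others.
* A delta `d` outside [−128, 127] is factored as `d = scale × q` over the
  scale set {2, 4, 8, 16, 32, 64, 128, 256} (3-bit code = log2(scale) − 1,
  smallest exact scale with |q| ≤ 127). When no exact factoring exists the
  sample is re-sent as AV — the codec stays bit-exact.
* The SF quotient follows the 3-bit scale code directly, with no `0`
  descriptor of its own; the SF unit (4 + 3 + 8 = 15 bits) is atomic.
* Samples outside the 18-bit range are coded GB: the value is lost (the
  only sanctioned loss) but the sample counter still advances, and the
  encoder re-syncs with an AV on the next valid sample.
* SpO2 and movement tokens are emitted immediately after the PPG token of
  the sample they are stamped on (SpO2 every 100 PPG samples, movements
  every 6000); on decode they are stamped at the most recent decoded PPG
  sample index.

## Worked example

Encoding the PPG samples `[1000, 1005, 1003, 1515, 1520, <artifact>, 1400]`
with one SpO2 reading (97%) and one movement count (3) produces a single
block whose first row has

```
counter      = 00 00 00 00          (first PPG sample of the recording)
useful bits  = 77 00                (0x0077 = 119 bits)
payload head = c0 1f 47 bc f8 00 0c 0a fe e4 80 05 b0 ...
```

The 119 useful bits parse as:

```
110 000000001111101000   AV 1000          first data value is absolute
11110 111100             SpO2 60          97% - 37 = 60
111110 0000000000000011  Move 3
0 00000101               DD +5            1000 -> 1005
0 11111110               DD -2            1005 -> 1003
1110 010 01000000        SF scale 8, q 64 1003 + 8*64 = 1515
0 00000101               DD +5            1515 -> 1520
10                       GB               artifact, value dropped
110 000000010101111000   AV 1400          re-sync after garbage
```

which reproduces the canonical row pattern
`110|AV|0|DD|0|DD|1110|SF|DD|0|DD|10|110|AV`. The frame header for this
block is `{"device_id": "UPNEA-0", "checksum": 120}`.

## Unpacked CSV dialect

`sleepglove codec unpack` writes columns `time_s, ppg, spo2, movements`;
SpO2/movement cells are empty except on their sampling instants, and PPG
cells are empty where samples were lost to garbage coding or corrupt
blocks.
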