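# Expression language

The `script.eval` op and the built-in script language share one expression
grammar. Operators dispatch through the op-matching engine, so the same
expression applies to scalars and to images (`+` on two images resolves to
`math.add`'s element-wise variant, on an image and a number to the
image-constant variant, and so on).

## Grammar (EBNF)

```ebnf
expr    = term { ("+" | "-") term } ;
term    = factor { ("*" | "/") factor } ;
factor  = "-" factor | postfix ;
postfix = primary [ "(" [ expr { "," expr } ] ")" ] ;
primary = NUMBER | STRING | IDENT | "(" expr ")" ;

NUMBER  = digits [ "." digits ] [ ("e"|"E") ["+"|"-"] digits ] ;
STRING  = '"' { character | '\"' | "\\" | "\n" | "\t" } '"' ;
IDENT   = letter { letter | digit | "_" } { "." letter { letter | digit | "_" } } ;
```

- Binary operators are left-associative; `*` and `/` bind tighter than
  `+` and `-`.
- `/` is real division on scalars (`5/2` is `2.5`); on integer images the
  real quotient is rounded half-to-even by the output cast.
- Calls `name(args…)` resolve `name` through the op registry: dotted names
  (`math.add`) match directly, bare names (`gauss`, `sub`, `mean`) match
  registered aliases.
- `+` with a string operand concatenates, rendering the other operand
  canonically (`"n=" + 3` is `"n=3"`).
- Unary minus negates scalars and multiplies images by −1.
- Identifiers are looked up in the binding environment; an unbound name is
  an error, as is any syntax error (reported with its character position).

## Script bodies

The built-in script language executes one `name = expression` statement per
line (blank lines and `#` comments are skipped); each assignment extends the
environment, and every declared output parameter must be assigned by the
end of the body.

```text
#@ string name
#@ int age
#@output string greeting
greeting = "Hello " + name + "! You are " + age
```
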